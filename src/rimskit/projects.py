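"""Project hierarchy operations.

Projects form a forest: every project has at most one parent, sibling names
are unique (case-sensitive), and each project is mirrored by one directory
on disk nested exactly as the tree is.  Projects carry free-text metadata
plus characteristic values constrained by the linked template, if any.
"""

from __future__ import annotations

import json

from .errors import (
    DuplicateNameError,
    NotFoundError,
    PermissionDeniedError,
    TreeError,
    ValidationError,
)
from .model import Breadcrumb, Project, Role, Template
from .permissions import can
from .repository import Repository, utc_now
from .templates import link_template, validate_value


def _check_sibling_name(repo: Repository, name: str, parent_id: int | None,
                        exclude_id: int | None = None) -> None:
    for sib in repo.children(parent_id):
        if sib.name == name and sib.id != exclude_id:
            where = ("the repository root" if parent_id is None
                     else f"project id {parent_id}")
            raise DuplicateNameError(
                f"a project named {name!r} already exists under {where}")


def create_project(repo: Repository, name: str, description: str = "",
                   parent_id: int | None = None, owner_id: int = 1,
                   template_id: int | None = None,
                   acronym: str | None = None) -> Project:
    """Create a project (and its mirrored directory).

    The owner must hold the Moderator role or above; the name must be
    nonempty and unique among its siblings.
    """
    owner = repo.get_user(owner_id)
    if owner.role < Role.MODERATOR:
        raise PermissionDeniedError(
            f"user {owner.username!r} (role {owner.role.name}) may not own "
            "projects; Moderator required")
    if not name.strip():
        raise ValidationError("project name must be nonempty")
    if parent_id is not None:
        repo.get_project(parent_id)  # raises on unknown parent
    _check_sibling_name(repo, name, parent_id)
    if template_id is not None:
        repo.get_template(template_id)

    with repo.transaction():
        cur = repo.db.execute(
            "INSERT INTO projects (name, acronym, description, parent_id, "
            "owner_id, created_at, dirname) VALUES (?, ?, ?, ?, ?, ?, '')",
            (name, acronym, description, parent_id, owner_id, utc_now()))
        pid = cur.lastrowid
        dirname = repo.unique_dirname(name, parent_id, pid)
        repo.db.execute(
            "UPDATE projects SET dirname = ? WHERE id = ?", (dirname, pid))
        repo.fs_mkdir(repo.project_dir(repo.get_project(pid)))
        if template_id is not None:
            link_template(repo, pid, template_id, owner_id)
    return repo.get_project(pid)


def edit_project(repo: Repository, project_id: int, changes: dict,
                 actor: int) -> Project:
    """Partial update of name / acronym / description / parent.

    Renaming re-checks sibling uniqueness and renames the mirrored
    directory; re-parenting re-checks the tree invariant and moves the
    directory.
    """
    project = repo.get_project(project_id)
    if not can(repo, actor, "edit", project):
        raise PermissionDeniedError(
            f"user {actor} may not edit project {project.name!r}")
    allowed = {"name", "acronym", "description", "parent_id"}
    unknown = set(changes) - allowed
    if unknown:
        raise ValidationError(f"unknown project fields: {sorted(unknown)}")

    new_name = changes.get("name", project.name)
    if not str(new_name).strip():
        raise ValidationError("project name must be nonempty")
    new_parent = changes.get("parent_id", project.parent_id)
    if new_parent is not None:
        repo.get_project(new_parent)
        if new_parent == project_id or new_parent in set(
                repo.subtree_ids(project_id)):
            raise TreeError("cannot move a project into its own subtree")
    _check_sibling_name(repo, new_name, new_parent, exclude_id=project_id)

    old_dir = repo.project_dir(project)
    with repo.transaction():
        repo.db.execute(
            "UPDATE projects SET name = ?, acronym = ?, description = ?, "
            "parent_id = ? WHERE id = ?",
            (new_name, changes.get("acronym", project.acronym),
             changes.get("description", project.description),
             new_parent, project_id))
        if new_name != project.name or new_parent != project.parent_id:
            dirname = repo.unique_dirname(new_name, new_parent, project_id)
            repo.db.execute(
                "UPDATE projects SET dirname = ? WHERE id = ?",
                (dirname, project_id))
            new_dir = repo.project_dir(repo.get_project(project_id))
            if new_dir != old_dir:
                repo.fs_move(old_dir, new_dir)
    return repo.get_project(project_id)


def delete_project(repo: Repository, project_id: int, actor: int) -> None:
    """Remove an empty project (no files, no sub-projects); owner or
    Administrator only.  Grants on the project are dropped with it."""
    project = repo.get_project(project_id)
    acting = repo.get_user(actor)
    if project.owner_id != actor and acting.role < Role.ADMINISTRATOR:
        raise PermissionDeniedError(
            "project deletion requires ownership or Administrator")
    if repo.children(project_id):
        raise ValidationError(
            f"project {project.name!r} has sub-projects and cannot be deleted")
    if repo.files_of(project_id):
        raise ValidationError(
            f"project {project.name!r} has files and cannot be deleted")
    pdir = repo.project_dir(project)
    with repo.transaction():
        repo.db.execute("DELETE FROM grants WHERE project_id = ?", (project_id,))
        repo.db.execute("DELETE FROM projects WHERE id = ?", (project_id,))
        repo.fs_rmdir(pdir)


def copy_project(repo: Repository, project_id: int, dest_parent_id: int | None,
                 actor: int) -> Project:
    """Deep-copy a project subtree under a new parent.

    Projects, managed files (bytes included), annotation and characteristic
    values and template links are all reproduced with fresh ids; grants are
    *not* copied, so a copy starts owner-only.  A sibling name collision at
    the destination is resolved by suffixing " (copy)", " (copy 2)", ...
    """
    src = repo.get_project(project_id)
    if not can(repo, actor, "read", src):
        raise PermissionDeniedError(
            f"user {actor} may not read project {src.name!r}")
    acting = repo.get_user(actor)
    if dest_parent_id is None:
        if acting.role < Role.MODERATOR:
            raise PermissionDeniedError(
                "copying to the repository root requires Moderator")
    else:
        dest = repo.get_project(dest_parent_id)
        if not can(repo, actor, "edit", dest):
            raise PermissionDeniedError(
                f"user {actor} may not edit project {dest.name!r}")
        if dest_parent_id in set(repo.subtree_ids(project_id)):
            raise TreeError("cannot copy a project into its own subtree")
    if acting.role < Role.MODERATOR:
        raise PermissionDeniedError(
            "a copy's owner must hold Moderator or above")

    name = src.name
    taken = {p.name for p in repo.children(dest_parent_id)}
    if name in taken:
        suffix = 1
        candidate = f"{name} (copy)"
        while candidate in taken:
            suffix += 1
            candidate = f"{name} (copy {suffix})"
        name = candidate

    def clone(node: Project, new_parent: int | None, new_name: str) -> int:
        cur = repo.db.execute(
            "INSERT INTO projects (name, acronym, description, parent_id, "
            "owner_id, template_id, created_at, dirname, characteristics) "
            "VALUES (?, ?, ?, ?, ?, ?, ?, '', ?)",
            (new_name, node.acronym, node.description, new_parent, actor,
             node.template_id, utc_now(),
             json.dumps(node.characteristic_values, sort_keys=True)))
        new_id = cur.lastrowid
        dirname = repo.unique_dirname(new_name, new_parent, new_id)
        repo.db.execute("UPDATE projects SET dirname = ? WHERE id = ?",
                        (dirname, new_id))
        new_proj = repo.get_project(new_id)
        repo.fs_mkdir(repo.project_dir(new_proj))
        src_dir = repo.project_dir(node)
        for mf in repo.files_of(node.id):
            data = (src_dir / mf.filename).read_bytes()
            repo.db.execute(
                "INSERT INTO files (project_id, filename, size_bytes, "
                "checksum, annotations) VALUES (?, ?, ?, ?, ?)",
                (new_id, mf.filename, mf.size_bytes, mf.checksum,
                 json.dumps(mf.annotation_values, sort_keys=True)))
            repo.fs_write(repo.project_dir(new_proj) / mf.filename, data)
        for child in repo.children(node.id):
            clone(child, new_id, child.name)
        return new_id

    with repo.transaction():
        new_root = clone(src, dest_parent_id, name)
    return repo.get_project(new_root)


def get_breadcrumb(repo: Repository, project_id: int) -> Breadcrumb:
    """Path of (id, name) pairs from a root project down to the target."""
    steps: list[tuple[int, str]] = []
    node: Project | None = repo.get_project(project_id)
    seen: set[int] = set()
    while node is not None:
        if node.id in seen:  # defensive: storage corruption only
            raise TreeError("cycle detected in project parent links")
        seen.add(node.id)
        steps.append((node.id, node.name))
        node = (repo.get_project(node.parent_id)
                if node.parent_id is not None else None)
    return Breadcrumb(steps=tuple(reversed(steps)))


def set_characteristic(repo: Repository, project_id: int, name: str,
                       value: str, actor: int) -> Project:
    """Set one project characteristic.

    Under a template the name must be a defined characteristic and the
    value must pass validation (value list membership, mandatory rule);
    without a template any key is accepted.
    """
    project = repo.get_project(project_id)
    if not can(repo, actor, "edit", project):
        raise PermissionDeniedError(
            f"user {actor} may not edit project {project.name!r}")
    if project.template_id is not None:
        tpl = repo.get_template(project.template_id)
        d = tpl.characteristic(name)
        if d is None:
            raise ValidationError(
                f"{name!r} is not a characteristic of template {tpl.name!r}")
        problem = validate_value(d, value)
        if problem is not None:
            raise ValidationError(problem)
    values = dict(project.characteristic_values)
    values[name] = value
    with repo.transaction():
        repo.db.execute(
            "UPDATE projects SET characteristics = ? WHERE id = ?",
            (json.dumps(values, sort_keys=True), project_id))
    return repo.get_project(project_id)


def search(repo: Repository, query: str, actor: int) -> list[Project | Template]:
    """Case-insensitive substring search over project names/descriptions and
    template names/descriptions/keywords, restricted to readable objects.
    An empty query returns nothing."""
    q = query.strip().lower()
    if not q:
        return []
    out: list[Project | Template] = []
    for p in repo.iter_projects():
        hay = f"{p.name}\n{p.description}".lower()
        if q in hay and can(repo, actor, "read", p):
            out.append(p)
    for t in repo.list_templates():
        hay = "\n".join([t.name, t.description, *t.keywords]).lower()
        if q in hay and can(repo, actor, "read", t):
            out.append(t)
    return out
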