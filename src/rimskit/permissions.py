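"""Role and grant based access control.

Four ordered roles — User < Moderator < Administrator < Superadministrator —
cap what a person can do globally; per-project read/edit grants to users or
groups open individual projects.  The capability matrix:

* **User** — acts only on projects granted to them (directly or through a
  group), at the granted level.
* **Moderator** — additionally creates and owns projects and templates; an
  owner holds read, edit and admin (grant management) on what they own.
* **Administrator** — additionally manages groups, manages users up to the
  Moderator role, and holds full access to every project and template.
* **Superadministrator** — everything, including role assignment to any level.

Grants do **not** flow down the project tree implicitly; the ``recursive``
flag of :func:`grant` is the explicit mechanism for opening a subtree.
A single decision function, :func:`can`, answers every access question;
managed files inherit the decision of their project.
"""

from __future__ import annotations

from .errors import DuplicateNameError, NotFoundError, PermissionDeniedError
from .model import (
    Grant,
    GrantLevel,
    Group,
    ManagedFile,
    Project,
    Role,
    Template,
    User,
)
from .repository import Repository


def create_user(repo: Repository, actor: int, username: str,
                role: Role = Role.USER) -> User:
    """Register a user account. Administrators may create accounts up to
    Moderator; only a Superadministrator may create Administrators."""
    acting = repo.get_user(actor)
    if acting.role < Role.ADMINISTRATOR:
        raise PermissionDeniedError("only Administrators may create users")
    if acting.role < Role.SUPERADMINISTRATOR and role > Role.MODERATOR:
        raise PermissionDeniedError(
            "an Administrator may not create users above Moderator")
    if not username.strip():
        raise ValueError("username must be nonempty")
    exists = repo.db.execute(
        "SELECT 1 FROM users WHERE username = ?", (username,)).fetchone()
    if exists:
        raise DuplicateNameError(f"username {username!r} already taken")
    with repo.transaction():
        cur = repo.db.execute(
            "INSERT INTO users (username, role) VALUES (?, ?)",
            (username, int(role)))
    return repo.get_user(cur.lastrowid)


def assign_role(repo: Repository, actor: int, user_id: int, role: Role) -> User:
    """Replace a user's role.

    A Superadministrator may assign any role; an Administrator may move
    users only within the User–Moderator range (neither promoting beyond
    Moderator nor touching anyone already above it).
    """
    acting = repo.get_user(actor)
    target = repo.get_user(user_id)
    if acting.role >= Role.SUPERADMINISTRATOR:
        pass
    elif acting.role >= Role.ADMINISTRATOR:
        if role > Role.MODERATOR or target.role > Role.MODERATOR:
            raise PermissionDeniedError(
                "an Administrator may only assign roles up to Moderator")
    else:
        raise PermissionDeniedError("role assignment requires Administrator")
    with repo.transaction():
        repo.db.execute(
            "UPDATE users SET role = ? WHERE id = ?", (int(role), user_id))
    return repo.get_user(user_id)


def create_group(repo: Repository, actor: int, name: str,
                 member_ids: list[int] | None = None) -> Group:
    """Create a named user group usable as a grant principal."""
    acting = repo.get_user(actor)
    if acting.role < Role.ADMINISTRATOR:
        raise PermissionDeniedError("group creation requires Administrator")
    if not name.strip():
        raise ValueError("group name must be nonempty")
    if repo.db.execute("SELECT 1 FROM groups WHERE name = ?", (name,)).fetchone():
        raise DuplicateNameError(f"group {name!r} already exists")
    members = list(dict.fromkeys(member_ids or []))
    for uid in members:
        repo.get_user(uid)  # raises NotFoundError on bad member
    with repo.transaction():
        cur = repo.db.execute("INSERT INTO groups (name) VALUES (?)", (name,))
        gid = cur.lastrowid
        for uid in members:
            repo.db.execute(
                "INSERT INTO group_members (group_id, user_id) VALUES (?, ?)",
                (gid, uid))
    return repo.get_group(gid)


def add_group_member(repo: Repository, actor: int, group_id: int,
                     user_id: int) -> Group:
    acting = repo.get_user(actor)
    if acting.role < Role.ADMINISTRATOR:
        raise PermissionDeniedError("group management requires Administrator")
    repo.get_group(group_id)
    repo.get_user(user_id)
    with repo.transaction():
        repo.db.execute(
            "INSERT OR IGNORE INTO group_members (group_id, user_id) "
            "VALUES (?, ?)", (group_id, user_id))
    return repo.get_group(group_id)


def grant(repo: Repository, actor: int, project_id: int, principal_id: int,
          level: GrantLevel, principal_kind: str = "user",
          recursive: bool = False) -> list[Grant]:
    """Grant read or edit on a project (optionally its whole subtree) to a
    user or group.  A higher pre-existing level is kept (edit wins over
    read)."""
    acting = repo.get_user(actor)
    project = repo.get_project(project_id)
    if acting.role < Role.ADMINISTRATOR and project.owner_id != actor:
        raise PermissionDeniedError(
            "granting requires project ownership or Administrator")
    if principal_kind == "user":
        repo.get_user(principal_id)
    elif principal_kind == "group":
        repo.get_group(principal_id)
    else:
        raise ValueError(f"unknown principal kind {principal_kind!r}")
    targets = repo.subtree_ids(project_id) if recursive else [project_id]
    out: list[Grant] = []
    with repo.transaction():
        for pid in targets:
            out.append(repo.upsert_grant(pid, principal_kind, principal_id, level))
    return out


def _granted_level(repo: Repository, user: User, project_id: int) -> GrantLevel | None:
    best: GrantLevel | None = None
    for g in repo.grants_for(project_id):
        applies = (
            (g.principal_kind == "user" and g.principal_id == user.id)
            or (g.principal_kind == "group" and g.principal_id in user.group_ids)
        )
        if applies and (best is None or g.level > best):
            best = g.level
    return best


def can(repo: Repository, user_id: int,
        action: str, target: Project | Template | ManagedFile) -> bool:
    """The single access decision: may ``user_id`` perform ``action``
    (``read`` | ``edit`` | ``admin``) on the target object?

    Files inherit their project's decision.  There is no implicit
    inheritance from parent projects.
    """
    if action not in ("read", "edit", "admin"):
        raise ValueError(f"unknown action {action!r}")
    user = repo.get_user(user_id)
    if user.role >= Role.ADMINISTRATOR:
        return True

    if isinstance(target, ManagedFile):
        target = repo.get_project(target.project_id)

    if isinstance(target, Template):
        if action == "read":
            return True  # templates are shared schemas, readable by all
        return target.owner_id == user.id

    if isinstance(target, Project):
        if target.owner_id == user.id:
            return True
        level = _granted_level(repo, user, target.id)
        if level is None:
            return False
        if action == "read":
            return True
        if action == "edit":
            return level >= GrantLevel.EDIT
        return False  # admin on a project needs ownership or Administrator

    raise NotFoundError(f"unsupported target {type(target).__name__}")
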