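"""Metadata templates: reusable, lockable minimum-information schemas.

A template bundles an ordered list of *characteristic* definitions (project
level metadata) and *annotation* definitions (file/sample level metadata).
Linking a template to a project enforces that schema on the project's
metadata from then on, and freezes the template itself: a template used by
any project can never be modified again, so previously validated records
cannot be silently invalidated.

Each definition may carry either an explicit default value or a closed value
list (never both); with a value list, its first entry acts as the effective
default and any stored value must be a member of the list.  A per-definition
``mandatory`` flag marks fields that must be nonempty for a project to count
as minimum-information compliant.
"""

from __future__ import annotations

import json

import yaml

from .errors import (
    DuplicateNameError,
    NotFoundError,
    PermissionDeniedError,
    TemplateLockedError,
    ValidationError,
)
from .model import FieldDef, LinkReport, Role, Template, Violation
from .repository import Repository
from .permissions import can


def validate_def(d: FieldDef) -> None:
    """A definition is valid when named, and default/value-list are not both set."""
    if not d.name.strip():
        raise ValidationError("definition name must be nonempty")
    if d.default_value is not None and d.value_list is not None:
        raise ValidationError(
            f"definition {d.name!r}: default value and value list are "
            "mutually exclusive")
    if d.value_list is not None and len(d.value_list) == 0:
        raise ValidationError(f"definition {d.name!r}: value list is empty")


def validate_value(d: FieldDef, value: str) -> str | None:
    """Check one value against one definition.

    Returns ``None`` when the value is acceptable, otherwise a description
    of the violation.  An empty value is acceptable iff the definition is
    not mandatory; a nonempty value must belong to the value list when one
    is defined.  Pure: no repository access.
    """
    if value == "":
        if d.mandatory:
            return f"{d.name!r} is mandatory but empty"
        return None
    if d.value_list is not None and value not in d.value_list:
        allowed = ", ".join(d.value_list)
        return f"{value!r} is not an allowed value of {d.name!r} ({allowed})"
    return None


def create_template(repo: Repository, name: str, keywords: list[str],
                    description: str, owner_id: int) -> Template:
    """Create an empty, unlocked template owned by a Moderator or above."""
    owner = repo.get_user(owner_id)
    if owner.role < Role.MODERATOR:
        raise PermissionDeniedError("template creation requires Moderator")
    if not name.strip():
        raise ValidationError("template name must be nonempty")
    if repo.db.execute(
            "SELECT 1 FROM templates WHERE name = ?", (name,)).fetchone():
        raise DuplicateNameError(f"template {name!r} already exists")
    with repo.transaction():
        cur = repo.db.execute(
            "INSERT INTO templates (name, owner_id, description, keywords) "
            "VALUES (?, ?, ?, ?)",
            (name, owner_id, description, json.dumps(list(keywords))))
    return repo.get_template(cur.lastrowid)


def add_def(repo: Repository, template_id: int, kind: str, d: FieldDef,
            actor: int) -> Template:
    """Append a characteristic or annotation definition to an unlocked
    template, preserving definition order."""
    if kind not in ("characteristic", "annotation"):
        raise ValueError(f"unknown def kind {kind!r}")
    tpl = repo.get_template(template_id)
    acting = repo.get_user(actor)
    if tpl.locked:
        raise TemplateLockedError(
            f"template {tpl.name!r} is used by a project and cannot be modified")
    if acting.role < Role.ADMINISTRATOR and tpl.owner_id != actor:
        raise PermissionDeniedError(
            "modifying a template requires ownership or Administrator")
    validate_def(d)
    existing = (tpl.characteristic_defs if kind == "characteristic"
                else tpl.annotation_defs)
    if any(e.name == d.name for e in existing):
        raise DuplicateNameError(
            f"{kind} {d.name!r} already defined in template {tpl.name!r}")
    with repo.transaction():
        repo.db.execute(
            "INSERT INTO template_defs (template_id, kind, position, name, "
            "description, default_value, value_list, mandatory, "
            "experimental_question) VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (template_id, kind, len(existing), d.name, d.description,
             d.default_value,
             json.dumps(list(d.value_list)) if d.value_list is not None else None,
             int(d.mandatory), int(d.experimental_question)))
    return repo.get_template(template_id)


def link_template(repo: Repository, project_id: int, template_id: int,
                  actor: int) -> LinkReport:
    """Bind a template to a project and lock the template.

    The project gains one characteristic slot per characteristic definition
    and every managed file already in the project receives the effective
    default of each annotation definition (explicit default, else first
    value-list entry, else empty).  A project's template cannot be replaced
    once set.
    """
    project = repo.get_project(project_id)
    tpl = repo.get_template(template_id)
    if not can(repo, actor, "edit", project):
        raise PermissionDeniedError(
            f"user {actor} may not edit project {project.name!r}")
    if project.template_id is not None:
        raise ValidationError(
            f"project {project.name!r} already has a template")
    char_names = {d.name for d in tpl.characteristic_defs}
    foreign = set(project.characteristic_values) - char_names
    if foreign:
        raise ValidationError(
            "project has characteristics outside the template: "
            + ", ".join(sorted(foreign)))

    chars = dict(project.characteristic_values)
    for d in tpl.characteristic_defs:
        chars.setdefault(d.name, d.effective_default())
    ann_defaults = {d.name: d.effective_default() for d in tpl.annotation_defs}

    with repo.transaction():
        repo.db.execute(
            "UPDATE projects SET template_id = ?, characteristics = ? "
            "WHERE id = ?",
            (template_id, json.dumps(chars, sort_keys=True), project_id))
        repo.db.execute(
            "UPDATE templates SET locked = 1 WHERE id = ?", (template_id,))
        for mf in repo.files_of(project_id):
            values = dict(ann_defaults)
            values.update({k: v for k, v in mf.annotation_values.items()
                           if k in ann_defaults})
            repo.set_file_annotations(mf.id, values)
    return LinkReport(
        characteristics_added=len(tpl.characteristic_defs),
        annotations_added=len(tpl.annotation_defs))


def copy_project_as_template(repo: Repository, project_id: int, new_name: str,
                             actor: int) -> Template:
    """Derive a fresh, unlocked template from a project's metadata schema.

    With a templated source the definitions are copied field-by-field from
    the source template; a template-less source yields blank definitions
    named after the observed characteristic keys and the union of file
    annotation keys.
    """
    project = repo.get_project(project_id)
    if not can(repo, actor, "read", project):
        raise PermissionDeniedError(
            f"user {actor} may not read project {project.name!r}")
    if project.template_id is not None:
        src = repo.get_template(project.template_id)
        char_defs = list(src.characteristic_defs)
        ann_defs = list(src.annotation_defs)
    else:
        char_defs = [FieldDef(name=k)
                     for k in sorted(project.characteristic_values)]
        ann_keys: set[str] = set()
        for mf in repo.files_of(project_id):
            ann_keys.update(mf.annotation_values)
        ann_defs = [FieldDef(name=k) for k in sorted(ann_keys)]
        if not char_defs and not ann_defs:
            raise ValidationError(
                f"project {project.name!r} has no metadata to derive a "
                "template from")
    tpl = create_template(repo, new_name, [], project.description, actor)
    for d in char_defs:
        tpl = add_def(repo, tpl.id, "characteristic", d, actor)
    for d in ann_defs:
        tpl = add_def(repo, tpl.id, "annotation", d, actor)
    return tpl


def check_mi_compliance(repo: Repository, project_id: int) -> list[Violation]:
    """Minimum-information audit of a templated project.

    Emits one violation per (file, annotation definition) whose stored
    value fails :func:`validate_value`, and one per mandatory
    characteristic that is missing or empty.  An empty list means the
    project record is compliant with its template.
    """
    project = repo.get_project(project_id)
    if project.template_id is None:
        raise NotFoundError(
            f"project {project.name!r} has no template to validate against")
    tpl = repo.get_template(project.template_id)
    violations: list[Violation] = []
    for d in tpl.characteristic_defs:
        if d.mandatory and not project.characteristic_values.get(d.name, ""):
            violations.append(Violation(
                scope="project", object_name=project.name, field_name=d.name,
                message=f"mandatory characteristic {d.name!r} is empty"))
    for mf in repo.files_of(project_id):
        for d in tpl.annotation_defs:
            problem = validate_value(d, mf.annotation_values.get(d.name, ""))
            if problem is not None:
                violations.append(Violation(
                    scope="file", object_name=mf.filename,
                    field_name=d.name, message=problem))
    return violations


# ---------------------------------------------------------------------------
# serialization — the documented YAML structure consumed by the CLI/fixtures


def _def_to_dict(d: FieldDef, kind: str) -> dict:
    out: dict = {"name": d.name}
    if d.description:
        out["description"] = d.description
    if d.default_value is not None:
        out["default_value"] = d.default_value
    if d.value_list is not None:
        out["value_list"] = list(d.value_list)
    if d.mandatory:
        out["mandatory"] = True
    if kind == "annotation" and d.experimental_question:
        out["experimental_question"] = True
    return out


def template_to_dict(tpl: Template) -> dict:
    return {
        "name": tpl.name,
        "keywords": list(tpl.keywords),
        "description": tpl.description,
        "characteristics": [_def_to_dict(d, "characteristic")
                            for d in tpl.characteristic_defs],
        "annotations": [_def_to_dict(d, "annotation")
                        for d in tpl.annotation_defs],
    }


def _def_from_dict(raw: dict) -> FieldDef:
    vl = raw.get("value_list")
    return FieldDef(
        name=str(raw["name"]),
        description=str(raw.get("description", "")),
        default_value=(str(raw["default_value"])
                       if "default_value" in raw else None),
        value_list=tuple(str(v) for v in vl) if vl is not None else None,
        mandatory=bool(raw.get("mandatory", False)),
        experimental_question=bool(raw.get("experimental_question", False)),
    )


def dump_template(tpl: Template) -> str:
    """Serialize a template definition to YAML."""
    return yaml.safe_dump(template_to_dict(tpl), sort_keys=False)


def load_template(repo: Repository, text: str, owner_id: int) -> Template:
    """Create a template from its YAML serialization."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "name" not in raw:
        raise ValidationError("template document must be a mapping with a name")
    tpl = create_template(
        repo, str(raw["name"]),
        [str(k) for k in raw.get("keywords", [])],
        str(raw.get("description", "")), owner_id)
    for entry in raw.get("characteristics", []):
        tpl = add_def(repo, tpl.id, "characteristic", _def_from_dict(entry),
                      owner_id)
    for entry in raw.get("annotations", []):
        tpl = add_def(repo, tpl.id, "annotation", _def_from_dict(entry),
                      owner_id)
    return tpl
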