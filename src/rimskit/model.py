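"""Domain types.

The catalog half of the system lives in a small relational store; these
dataclasses are the in-memory view of its rows.  Experimental data files are
opaque blobs on disk; only their registration (name, size, checksum) and
their annotation values live here.

Metadata comes in two kinds, mirroring common minimum-information practice:

* *characteristics* describe a project as a whole (organism, platform, ...);
* *annotations* describe one managed file / sample (clinical variables, ...).

Both kinds can be bound to a reusable :class:`Template`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Role(enum.IntEnum):
    """Ordered user roles; capability sets are nested along this order."""

    USER = 0
    MODERATOR = 1
    ADMINISTRATOR = 2
    SUPERADMINISTRATOR = 3

    @classmethod
    def parse(cls, text: str) -> "Role":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown role: {text!r}") from None


class GrantLevel(enum.IntEnum):
    """Per-project access levels; edit implies read."""

    READ = 1
    EDIT = 2

    @classmethod
    def parse(cls, text: str) -> "GrantLevel":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown grant level: {text!r}") from None


@dataclass(frozen=True)
class User:
    id: int
    username: str
    role: Role
    group_ids: tuple[int, ...] = ()


@dataclass(frozen=True)
class Group:
    id: int
    name: str
    member_ids: tuple[int, ...] = ()


@dataclass(frozen=True)
class Grant:
    project_id: int
    principal_kind: str  # "user" | "group"
    principal_id: int
    level: GrantLevel


@dataclass(frozen=True)
class Project:
    id: int
    name: str
    description: str
    owner_id: int
    created_at: str  # UTC, ISO-8601
    parent_id: int | None = None
    acronym: str | None = None
    template_id: int | None = None
    dirname: str = ""
    characteristic_values: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ManagedFile:
    id: int
    project_id: int
    filename: str
    size_bytes: int
    checksum: str
    annotation_values: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Breadcrumb:
    """Path of (project id, name) pairs from a root project to a target."""

    steps: tuple[tuple[int, str], ...]

    def __str__(self) -> str:
        return " -> ".join(name for _, name in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class FieldDef:
    """One metadata field definition.

    ``default_value`` and ``value_list`` are mutually exclusive ways to
    pre-fill and constrain values: a closed value list both restricts input
    and supplies its first entry as the effective default.
    ``experimental_question`` flags the annotation variables encoding the
    biological question a dataset addresses (annotations only).
    """

    name: str
    description: str = ""
    default_value: str | None = None
    value_list: tuple[str, ...] | None = None
    mandatory: bool = False
    experimental_question: bool = False

    def effective_default(self) -> str:
        if self.default_value is not None:
            return self.default_value
        if self.value_list:
            return self.value_list[0]
        return ""


# Characteristic and annotation definitions share one shape; the kind is the
# list a def belongs to.
CharacteristicDef = FieldDef
AnnotationDef = FieldDef


@dataclass(frozen=True)
class Template:
    id: int
    name: str
    owner_id: int
    description: str = ""
    keywords: tuple[str, ...] = ()
    characteristic_defs: tuple[FieldDef, ...] = ()
    annotation_defs: tuple[FieldDef, ...] = ()
    locked: bool = False

    def characteristic(self, name: str) -> FieldDef | None:
        return next((d for d in self.characteristic_defs if d.name == name), None)

    def annotation(self, name: str) -> FieldDef | None:
        return next((d for d in self.annotation_defs if d.name == name), None)


@dataclass(frozen=True)
class LinkReport:
    """Counts reported when a template is linked to a project."""

    characteristics_added: int
    annotations_added: int


@dataclass(frozen=True)
class Violation:
    """One minimum-information compliance failure."""

    scope: str  # "file" | "project"
    object_name: str  # filename or project name
    field_name: str
    message: str


@dataclass
class ImportReport:
    """Outcome of a bulk annotation update.

    Counts record *changes*, not touches: re-importing an unchanged export
    yields the zero report.
    """

    files_edited: int = 0
    values_updated: int = 0
    violations: list[Violation] = field(default_factory=list)
    unknown_files: list[str] = field(default_factory=list)

    def message(self) -> str:
        return (
            f"{self.files_edited} file(s) correctly edited - "
            f"{self.values_updated} file annotation(s) updated"
        )


@dataclass(frozen=True)
class MirrorIssue:
    """One disagreement between the catalog and the on-disk tree."""

    kind: str  # missing_dir | missing_file | orphan_path | checksum_mismatch
    path: str
    object_id: int | None = None


@dataclass(frozen=True)
class SnapshotRecord:
    id: int
    project_id: int
    created_at: str
    archive_path: str
    manifest: tuple[tuple[str, str], ...]  # (relative path, checksum)
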