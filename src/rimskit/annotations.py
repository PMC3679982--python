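"""Delimited annotation tables: bulk import/export of file metadata.

The interchange format is a header row plus one row per managed file.  The
first column identifies the file (its registered filename); every other
column is an annotation name.  The default dialect is tab-delimited UTF-8
with LF line endings and no quoting (the conventional ``annotation.txt``
export); a comma dialect with RFC-4180 quoting is selectable.

Import counts *changes*, not touches: a cell only counts when the stored
value actually differs, so re-importing an unmodified export reports zero
files edited and zero values updated.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .errors import (
    NotFoundError,
    PermissionDeniedError,
    TableError,
    ValidationError,
)
from .model import ImportReport, Violation
from .permissions import can
from .repository import Repository
from .templates import validate_value

FILE_COLUMN = "Filename"
DIALECTS = ("tab", "comma")


@dataclass
class AnnotationTable:
    """Parsed annotation table: unique headers, rectangular rows, first
    column = file identifier."""

    header: list[str]
    rows: list[list[str]] = field(default_factory=list)

    @property
    def annotation_names(self) -> list[str]:
        return self.header[1:]


def _delimiter(dialect: str) -> str:
    if dialect == "tab":
        return "\t"
    if dialect == "comma":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def parse_table(text: str, dialect: str = "tab") -> AnnotationTable:
    """Parse delimited text into an :class:`AnnotationTable`.

    Trailing blank lines are ignored and cell whitespace is trimmed.
    Ragged rows, duplicate header names, an empty header and empty file
    identifiers are all errors naming the offending line.
    """
    if not text.strip():
        raise TableError("annotation table is empty")
    delim = _delimiter(dialect)
    if dialect == "comma":
        reader = csv.reader(io.StringIO(text), delimiter=delim)
        raw_rows = [(i + 1, row) for i, row in enumerate(reader)]
    else:
        raw_rows = [(i + 1, line.split(delim))
                    for i, line in enumerate(text.split("\n"))]
    # drop blank trailing / interior empty lines
    rows = [(n, [c.strip() for c in cells]) for n, cells in raw_rows
            if any(c.strip() for c in cells)]
    if not rows:
        raise TableError("annotation table is empty")
    _, header = rows[0]
    if not header or not header[0] or any(not h for h in header):
        raise TableError("line 1: header names must all be nonempty")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise TableError(f"line 1: duplicate header name(s): {', '.join(dupes)}")
    body: list[list[str]] = []
    for lineno, cells in rows[1:]:
        if len(cells) != len(header):
            raise TableError(
                f"line {lineno}: expected {len(header)} cells, got {len(cells)}")
        if not cells[0]:
            raise TableError(f"line {lineno}: empty file identifier")
        body.append(cells)
    return AnnotationTable(header=header, rows=body)


def format_table(table: AnnotationTable, dialect: str = "tab") -> str:
    """Serialize a table (UTF-8 text, LF line endings).

    The tab dialect writes cells verbatim with no quoting, so cells must
    not contain tabs or newlines; the comma dialect quotes per RFC 4180.
    """
    delim = _delimiter(dialect)
    if dialect == "comma":
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter=delim, lineterminator="\n")
        writer.writerow(table.header)
        writer.writerows(table.rows)
        return buf.getvalue()
    lines = []
    for row in [table.header, *table.rows]:
        for cell in row:
            if "\t" in cell or "\n" in cell:
                raise TableError(
                    f"cell {cell!r} contains the delimiter; use the comma dialect")
        lines.append(delim.join(row))
    return "\n".join(lines) + "\n"


def export_table(repo: Repository, project_id: int, actor: int,
                 dialect: str | None = None,
                 _skip_permission: bool = False) -> str:
    """Export a project's annotation table as delimited text.

    One row per managed file, sorted by filename; columns are the file
    identifier followed by the template's annotation definitions in
    definition order (or the sorted union of observed keys for a
    template-less project).  Empty values export as empty cells.
    """
    project = repo.get_project(project_id)
    if not _skip_permission and not can(repo, actor, "read", project):
        raise PermissionDeniedError(
            f"user {actor} may not read project {project.name!r}")
    files = repo.files_of(project_id)  # already filename-sorted
    if project.template_id is not None:
        tpl = repo.get_template(project.template_id)
        columns = [d.name for d in tpl.annotation_defs]
    else:
        keys: set[str] = set()
        for mf in files:
            keys.update(mf.annotation_values)
        columns = sorted(keys)
    table = AnnotationTable(header=[FILE_COLUMN, *columns])
    for mf in files:
        table.rows.append(
            [mf.filename, *(mf.annotation_values.get(c, "") for c in columns)])
    return format_table(table, dialect or repo.config.get("dialect", "tab"))


def import_table(repo: Repository, project_id: int,
                 table: AnnotationTable | str, actor: int,
                 dialect: str | None = None) -> ImportReport:
    """Bulk-update file annotations from a table.

    Rows are matched to managed files by exact filename.  Every matched
    cell that passes validation and differs from the stored value replaces
    it; invalid cells are skipped and reported as violations; identifiers
    matching no file are reported in ``unknown_files``.  Under a template,
    any header column that is not a template annotation aborts the whole
    import, and matching no row at all is an error.
    """
    project = repo.get_project(project_id)
    if not can(repo, actor, "edit", project):
        raise PermissionDeniedError(
            f"user {actor} may not edit project {project.name!r}")
    if isinstance(table, str):
        table = parse_table(table, dialect or repo.config.get("dialect", "tab"))

    defs = None
    if project.template_id is not None:
        tpl = repo.get_template(project.template_id)
        defs = {d.name: d for d in tpl.annotation_defs}
        foreign = [c for c in table.annotation_names if c not in defs]
        if foreign:
            raise ValidationError(
                "table columns not defined by template "
                f"{tpl.name!r}: {', '.join(foreign)}")

    by_name = {mf.filename: mf for mf in repo.files_of(project_id)}
    report = ImportReport()
    pending: dict[int, dict[str, str]] = {}
    current: dict[int, dict[str, str]] = {}
    for row in table.rows:
        ident, cells = row[0], row[1:]
        mf = by_name.get(ident)
        if mf is None:
            report.unknown_files.append(ident)
            continue
        values = pending.get(mf.id)
        if values is None:
            values = dict(mf.annotation_values)
            current[mf.id] = dict(values)
            pending[mf.id] = values
        for name, cell in zip(table.annotation_names, cells):
            if defs is not None:
                problem = validate_value(defs[name], cell)
                if problem is not None:
                    report.violations.append(Violation(
                        scope="file", object_name=ident, field_name=name,
                        message=problem))
                    continue
            if values.get(name, "") != cell:
                values[name] = cell

    if not pending:
        raise NotFoundError("no table row matched a file of the project")

    with repo.transaction():
        for fid, values in pending.items():
            before = current[fid]
            changed = sum(
                1 for k in set(before) | set(values)
                if before.get(k, "") != values.get(k, ""))
            if changed:
                report.files_edited += 1
                report.values_updated += changed
                repo.set_file_annotations(fid, values)
    return report


def set_default_annotations(repo: Repository, project_id: int,
                            values: dict[str, str], actor: int) -> ImportReport:
    """Set the given annotations on every file of the project (where they
    differ), e.g. to pre-fill a constant like the organism.  Keys must be
    template annotation names when a template is linked."""
    project = repo.get_project(project_id)
    if not can(repo, actor, "edit", project):
        raise PermissionDeniedError(
            f"user {actor} may not edit project {project.name!r}")
    if project.template_id is not None:
        tpl = repo.get_template(project.template_id)
        defs = {d.name: d for d in tpl.annotation_defs}
        for name, value in values.items():
            if name not in defs:
                raise ValidationError(
                    f"{name!r} is not an annotation of template {tpl.name!r}")
            problem = validate_value(defs[name], value)
            if problem is not None:
                raise ValidationError(problem)
    report = ImportReport()
    with repo.transaction():
        for mf in repo.files_of(project_id):
            stored = dict(mf.annotation_values)
            changed = 0
            for name, value in values.items():
                if stored.get(name, "") != value:
                    stored[name] = value
                    changed += 1
            if changed:
                report.files_edited += 1
                report.values_updated += changed
                repo.set_file_annotations(mf.id, stored)
    return report
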