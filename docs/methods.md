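# Methods and design notes

## The system in one paragraph

rimskit separates a study's *metadata* from its *data*. Metadata — the
project hierarchy, characteristics, annotations, templates, users, grants,
snapshot records — lives in an embedded SQLite catalog under
`<root>/.rimskit/`. Data files are opaque blobs stored in a directory tree
that mirrors the project hierarchy one-to-one. This duality keeps the
catalog schema technology-independent (nothing in it knows what a CEL file
is) while leaving the data browsable and backup-friendly with ordinary file
tools. Every mutating operation couples the two sides transactionally, and
`mirror_check` can audit the coupling exhaustively at any time.

## Transactional mirroring

Each operation runs inside a scope that opens a SQLite transaction and keeps
an undo log of file-system actions (`mkdir`, file writes, renames). On any
exception the transaction is rolled back and the undo log replayed in
reverse, so a failed operation is a no-op on both sides. This is tested by
injecting write failures mid-import and mid-rename and asserting the
catalog, the directory tree and `mirror_check` are all unchanged. The
repository is single-writer by design; concurrent multi-writer access is out
of scope.

Project directories are named by a slug of the project name (every
non-alphanumeric character becomes `_`), with the project id appended when
two sibling names collapse onto the same slug. Renaming or moving a project
renames/moves its directory in the same transaction.

## Templates and minimum information

A template is an ordered list of characteristic definitions plus an ordered
list of annotation definitions (order is meaningful: it is the column order
of exported tables). A definition carries either an explicit default value
or a closed value list, never both; with a value list the first entry is the
*effective default*, and any nonempty stored value must be a list member.
The `mandatory` flag realizes "this field must be provided" as a concrete
mechanism: `check_mi_compliance` reports one violation per (file, annotation
definition) whose stored value fails validation and one per mandatory
characteristic left empty.

Linking a template to a project (a) sets the project's schema permanently —
a template cannot be replaced once set, because existing annotation values
would silently orphan; (b) locks the template forever, so records validated
against it cannot be invalidated later; (c) populates the project's
characteristic slots and every existing file's annotations with the
effective defaults. Linking is refused if the project already holds
free-form characteristic keys outside the template, to avoid silent data
loss. Files imported after linking receive the defaults as well.

## Permissions

Roles are strictly ordered and capability sets are nested: User < Moderator
(may create and own projects/templates; an owner holds read/edit/admin on
what they own) < Administrator (manages groups and users up to Moderator,
full access to all projects and templates) < Superadministrator
(everything). The choice that Administrators see *all* projects is a design
decision, made so that "gradually increasing permissions" has an
unsurprising meaning; the ordered-capability property is enforced by a
monotonicity test that sweeps a probe user through all four roles against
randomized grant sets.

Per-project grants name a user or a group and a level (`read` < `edit`;
edit implies read, and re-granting a lower level never downgrades). Grants
do not propagate down the tree implicitly — the `recursive` flag of
`grant()` is the explicit mechanism — so confidential sub-projects can
coexist under shared parents. Authentication is out of scope: callers and
the CLI (`--as`) supply an already-authenticated username.

## Annotation tables

The interchange format is a header row plus one row per file; the first
column is the file identifier (exact filename match by default), remaining
columns are annotation names. The default dialect is tab-delimited with no
quoting — annotation values in clinical tables routinely contain commas —
with an RFC-4180 comma dialect selectable. Exports are deterministic:
rows sorted by filename, columns in template definition order, UTF-8, LF.

Import semantics are designed around one idempotence property: importing an
unchanged export reports zero. Therefore `files_edited` counts files with at
least one *changed* cell and `values_updated` counts changed cells, verified
in tests against a brute-force before/after matrix diff and under row
permutations. Cells failing validation are skipped and reported as
violations; unknown identifiers are reported but do not abort; an unknown
*column* under a template aborts the whole import, because the template is
the MI contract.

## Snapshots

A snapshot freezes a project subtree into a zip archive containing every
managed file (paths mirroring the sub-project structure), one exported
`annotation.txt` per project, and a `manifest.json` with each project's
name, description, characteristics and template reference. Members are
written in sorted order with fixed timestamps and no compression, so an
unchanged project snapshots to a byte-identical archive — snapshot diffing
reduces to file comparison. The snapshot record stores a (path, checksum)
manifest covering every member; tests re-verify each checksum against the
archive. Snapshots include the whole subtree, since a freeze of a study that
silently dropped its sub-projects would be misleading for publication.

## Synthetic fixtures

The generator (`rimskit.fixtures`) emulates a 198-sample breast-cancer
microarray series: placeholder files `sample_001.CEL` ... `sample_198.CEL`
of a few hundred seeded random bytes each (data files are opaque blobs, so
content is irrelevant), a 198-row tab-delimited clinical annotation table,
and a matching template definition. Two presets reflect the two schema
sizes that matter: `worked_example_link` carries the five study
characteristics (Author, Original GEO/ArrayExpress Accession Number,
Organism, Platform Vendor, Platform Type) and six clinical annotations with
`e.dmfs`/`t.dmfs` flagged as experimental questions; `worked_example_import`
carries sixteen annotation columns so that a full first import updates
198 × 16 = 3168 values. The fourteen column names beyond `e.dmfs`/`t.dmfs`
are synthetic clinical-style reconstructions (age, grade, tumor size,
ER/node status, follow-up times, ...), chosen once for plausibility; only
the count matters to the arithmetic. Same preset and seed give byte-identical
outputs.

What the fixtures do *not* emulate: real CEL content, messy real-world
tables (ragged encodings, spreadsheet artifacts), very large files, or
concurrent users. Passing tests demonstrate the bookkeeping contracts
(counts, mirroring, locking, permissions), not robustness to arbitrary
real-world input.

## Numerical and procedural choices

- Checksums: SHA-256 (configurable per repository at init).
- Timestamps: UTC, ISO-8601.
- Archive type detection by magic bytes, not extension; zip, tar and tar.gz
  are accepted, anything else is imported as a single opaque file.
- Archive internal directories are flattened to basenames (files live flat
  in a project directory); basename collisions, and collisions with existing
  files, reject the whole import atomically rather than renaming — imports
  are provenance-checksummed, so silent renames are worse than a retry.
- Copying a project deep-copies the subtree with fresh ids, keeps template
  links and metadata, and does **not** copy grants (least privilege); a name
  collision at the destination appends " (copy)", " (copy 2)", ....
- Sibling project names are unique (case-sensitive); empty search queries
  return nothing; project deletion is allowed only for empty projects.
- A fresh repository is seeded with a Superadministrator account `admin` so
  it is administrable without an external user system.

## Problem sizes used in tests

The test suite and the acceptance script run the full 198-file series
(≈200 small files, a 198 × 16 table) plus randomized walks of ~100 mixed
operations and property checks at 25–60 examples; the complete suite runs
in a few seconds on one CPU.

## Known limitations

- Single-writer, embedded store: no client-server DBMS, no locking across
  processes.
- No streaming of multi-gigabyte uploads; archive members are buffered in
  memory during import.
- No authentication, sessions, LDAP or e-mail; no web interface.
- File matching on annotation import is by exact filename (an internal-id
  mode would be a straightforward extension).
- Snapshot archives assume project files are not named `annotation.txt` or
  `manifest.json`; such names would collide inside the archive.
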