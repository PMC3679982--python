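# rimskit

**rimskit** is a headless research information management system (RIMS) for
multi-technology laboratories: a Python library plus a `rimskit` command-line
tool that organizes heterogeneous experimental data files into a hierarchy of
projects, enforces minimum-information (MI) style metadata through reusable
templates, and shares everything under fine-grained role/group permissions.

It is aimed at small research groups that need one system for all their data
(microarray, flow cytometry, proteomics, sequencing, ...) without running a
web stack: the data files themselves are treated as opaque blobs, so nothing
in the system is technology-specific.

## The model

- **Project** — the organizational unit. Projects form a tree, and that tree
  is *mirrored on the file system*: one directory per project, nested exactly
  as the hierarchy, with each managed file stored in its project's directory.
  Only metadata lives in the embedded SQLite catalog; your data stays plain
  files you can inspect and back up. `rimskit fsck` verifies catalog and disk
  agree, down to checksums.
- **Managed file** — a registered data file (name, size, content checksum)
  carrying *annotations*: per-sample metadata such as clinical variables.
  Projects carry *characteristics*: study-level metadata such as organism or
  platform.
- **Template** — a reusable, ordered schema of characteristic and annotation
  definitions. A definition may carry a default value or a closed value list
  (the first list entry acts as the default); a `mandatory` flag makes a
  field required for MI compliance, and an `experimental question` flag marks
  the variables encoding the biological question. A template locks forever
  the moment any project uses it, so validated records cannot drift.
- **Permissions** — four ordered roles
  (User < Moderator < Administrator < Superadministrator) plus per-project
  read/edit grants to users or groups. Grants do not flow down the tree
  implicitly; recursive granting is explicit.
- **Annotation tables** — tab-delimited (or CSV) tables, one row per file,
  bulk-import/export per project. Import counts *changes*, not touches.
- **Snapshots** — immutable, deterministic zip freezes of a project subtree
  (data files + annotation tables + manifest) for publication.

## Worked example

A breast-cancer microarray series of 198 samples (one CEL file each) with a
16-variable clinical annotation table. The bundled fixture generator creates
a synthetic stand-in for the series, so the session runs anywhere:

```python
from pathlib import Path
import rimskit as rk

fx = rk.generate(rk.FixtureSpec(root=Path("fx"),
                                preset="worked_example_import", seed=1))

repo = rk.Repository.init(Path("repo"))
admin = repo.find_user("admin")
meta = rk.create_project(repo, "Meta_Breast_Cancer_Transcriptome",
                         owner_id=admin.id)
gse = rk.create_project(repo, "GSE7390 (Desmedt et al.)",
                        parent_id=meta.id, owner_id=admin.id)

files = rk.import_files(repo, gse.id, fx.archive, admin.id)   # 198 files
tpl = rk.load_template(repo, fx.template.read_text(), admin.id)
rk.link_template(repo, gse.id, tpl.id, admin.id)
report = rk.import_table(repo, gse.id, fx.table.read_text(), admin.id)
print(report.message())
print("mirror issues:", len(rk.mirror_check(repo, verify_checksums=True)))
```

prints

```
198 file(s) correctly edited - 3168 file annotation(s) updated
mirror issues: 0
```

— every one of the 198 files was edited and all 198 × 16 = 3168 annotation
cells changed (they start at the template defaults), and the on-disk mirror
still agrees with the catalog. Re-running the import prints
`0 file(s) correctly edited - 0 file annotation(s) updated`, because the
counts record changes, not touches.

The same session from the shell:

```
rimskit init repo
export RIMSKIT_REPO=repo
rimskit project add Meta_Breast_Cancer_Transcriptome
rimskit project add "GSE7390 (Desmedt et al.)" --parent Meta_Breast_Cancer_Transcriptome
rimskit files import "GSE7390 (Desmedt et al.)" fx/files.zip
rimskit template load fx/template.yaml
rimskit template link "GSE7390 (Desmedt et al.)" "Breast Cancer Clinical Import Template"
rimskit annot import "GSE7390 (Desmedt et al.)" fx/annotation.txt
rimskit perm grant "GSE7390 (Desmedt et al.)" somebody --level read
rimskit snapshot Meta_Breast_Cancer_Transcriptome
rimskit fsck --checksums
```

## Layout

| module | contents |
| --- | --- |
| `rimskit.model` | domain dataclasses (Project, ManagedFile, Template, ...) |
| `rimskit.repository` | SQLite catalog + mirrored tree, archive import, fsck, snapshots |
| `rimskit.projects` | hierarchy operations, breadcrumbs, search |
| `rimskit.templates` | template definitions, locking, validation, MI audit |
| `rimskit.permissions` | roles, groups, grants, the `can()` decision |
| `rimskit.annotations` | annotation table parsing, export, bulk import |
| `rimskit.fixtures` | deterministic synthetic study generator |
| `rimskit.cli` | the `rimskit` command |

See `docs/methods.md` for design notes and limitations.
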