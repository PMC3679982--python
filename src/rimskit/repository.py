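"""Repository: embedded relational catalog + mirrored file-system tree.

A repository is a directory.  Catalog data (projects, templates, users,
grants, file registrations, snapshots) lives in a SQLite database under
``<root>/.rimskit/``; experimental data files live as plain files in a
directory tree that mirrors the project hierarchy exactly — one directory per
project, nested as the projects are, each managed file stored in its
project's directory under its registered filename.  Everything outside
``.rimskit/`` is therefore user-visible data, and :func:`mirror_check` can
verify the two sides agree at any time.

Mutations couple the catalog and the disk transactionally: every operation
runs inside :meth:`Repository.transaction`, which rolls back the SQLite
transaction *and* undoes any file-system changes if anything raises, so a
failed operation leaves both sides untouched.
"""

from __future__ import annotations

import hashlib
import io
import json
import re
import shutil
import sqlite3
import tarfile
import zipfile
from contextlib import contextmanager
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Iterator

import yaml

from .errors import (
    ArchiveError,
    DuplicateNameError,
    NotFoundError,
    PermissionDeniedError,
    RepositoryError,
)
from .model import (
    FieldDef,
    Grant,
    GrantLevel,
    Group,
    ManagedFile,
    MirrorIssue,
    Project,
    Role,
    SnapshotRecord,
    Template,
    User,
)

INTERNAL_DIR = ".rimskit"
CONFIG_NAME = "config.yaml"
DB_NAME = "catalog.sqlite"
SNAPSHOT_DIR = "snapshots"

DEFAULT_CONFIG = {"checksum": "sha256", "dialect": "tab"}

_SCHEMA = """
CREATE TABLE IF NOT EXISTS users (
    id INTEGER PRIMARY KEY,
    username TEXT NOT NULL UNIQUE,
    role INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS groups (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS group_members (
    group_id INTEGER NOT NULL REFERENCES groups(id),
    user_id INTEGER NOT NULL REFERENCES users(id),
    PRIMARY KEY (group_id, user_id)
);
CREATE TABLE IF NOT EXISTS projects (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    acronym TEXT,
    description TEXT NOT NULL DEFAULT '',
    parent_id INTEGER REFERENCES projects(id),
    owner_id INTEGER NOT NULL REFERENCES users(id),
    template_id INTEGER REFERENCES templates(id),
    created_at TEXT NOT NULL,
    dirname TEXT NOT NULL,
    characteristics TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS files (
    id INTEGER PRIMARY KEY,
    project_id INTEGER NOT NULL REFERENCES projects(id),
    filename TEXT NOT NULL,
    size_bytes INTEGER NOT NULL,
    checksum TEXT NOT NULL,
    annotations TEXT NOT NULL DEFAULT '{}',
    UNIQUE (project_id, filename)
);
CREATE TABLE IF NOT EXISTS templates (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    owner_id INTEGER NOT NULL REFERENCES users(id),
    description TEXT NOT NULL DEFAULT '',
    keywords TEXT NOT NULL DEFAULT '[]',
    locked INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS template_defs (
    id INTEGER PRIMARY KEY,
    template_id INTEGER NOT NULL REFERENCES templates(id),
    kind TEXT NOT NULL CHECK (kind IN ('characteristic', 'annotation')),
    position INTEGER NOT NULL,
    name TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT '',
    default_value TEXT,
    value_list TEXT,
    mandatory INTEGER NOT NULL DEFAULT 0,
    experimental_question INTEGER NOT NULL DEFAULT 0,
    UNIQUE (template_id, kind, name)
);
CREATE TABLE IF NOT EXISTS grants (
    project_id INTEGER NOT NULL REFERENCES projects(id),
    principal_kind TEXT NOT NULL CHECK (principal_kind IN ('user', 'group')),
    principal_id INTEGER NOT NULL,
    level INTEGER NOT NULL,
    PRIMARY KEY (project_id, principal_kind, principal_id)
);
CREATE TABLE IF NOT EXISTS snapshots (
    id INTEGER PRIMARY KEY,
    project_id INTEGER NOT NULL REFERENCES projects(id),
    created_at TEXT NOT NULL,
    archive_path TEXT NOT NULL,
    manifest TEXT NOT NULL
);
"""


def utc_now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def slugify(name: str) -> str:
    """Directory-safe name: every non-alphanumeric character becomes '_'."""
    return re.sub(r"[^A-Za-z0-9]", "_", name)


def checksum_bytes(data: bytes, algorithm: str = "sha256") -> str:
    h = hashlib.new(algorithm)
    h.update(data)
    return h.hexdigest()


class Repository:
    """Open handle on a repository: catalog connection + root directory."""

    def __init__(self, root: Path, db_path: Path, config: dict):
        self.root = Path(root)
        self.db_path = Path(db_path)
        self.config = config
        self.db = sqlite3.connect(self.db_path, isolation_level=None)
        self.db.row_factory = sqlite3.Row
        self.db.execute("PRAGMA foreign_keys = ON")
        self._txn_depth = 0
        self._undo: list[Callable[[], None]] = []

    # -- lifecycle -----------------------------------------------------

    @classmethod
    def init(cls, root: str | Path, db_path: str | Path | None = None,
             config: dict | None = None) -> "Repository":
        """Create a new repository, or re-open ``root`` if it already is one.

        ``root`` must be absent, empty, or an existing repository; a
        non-empty foreign directory is refused.
        """
        root = Path(root)
        internal = root / INTERNAL_DIR
        if (internal / CONFIG_NAME).exists():
            return cls.open(root)
        if root.exists() and any(root.iterdir()):
            raise RepositoryError(
                f"{root} exists, is not empty and is not a repository")
        cfg = dict(DEFAULT_CONFIG)
        if config:
            cfg.update(config)
        root.mkdir(parents=True, exist_ok=True)
        internal.mkdir()
        (internal / SNAPSHOT_DIR).mkdir()
        db_path = Path(db_path) if db_path else internal / DB_NAME
        cfg["db_path"] = str(db_path)
        with open(internal / CONFIG_NAME, "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh)
        repo = cls(root, db_path, cfg)
        repo.db.executescript(_SCHEMA)
        # bootstrap account so that a fresh repository is administrable
        repo.db.execute(
            "INSERT INTO users (username, role) VALUES (?, ?)",
            ("admin", int(Role.SUPERADMINISTRATOR)),
        )
        return repo

    @classmethod
    def open(cls, root: str | Path) -> "Repository":
        root = Path(root)
        cfg_file = root / INTERNAL_DIR / CONFIG_NAME
        if not cfg_file.exists():
            raise RepositoryError(f"{root} is not a repository")
        with open(cfg_file, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        repo = cls(root, Path(cfg["db_path"]), cfg)
        repo.db.executescript(_SCHEMA)
        return repo

    def close(self) -> None:
        self.db.close()

    # -- transactions coupling catalog and disk ------------------------

    @contextmanager
    def transaction(self) -> Iterator[None]:
        """All-or-nothing scope: on exception the SQLite transaction is
        rolled back and registered file-system changes are undone in
        reverse order."""
        if self._txn_depth > 0:  # nested scope joins the outer transaction
            self._txn_depth += 1
            try:
                yield
            finally:
                self._txn_depth -= 1
            return
        self._txn_depth = 1
        self._undo = []
        self.db.execute("BEGIN")
        try:
            yield
        except BaseException:
            self.db.execute("ROLLBACK")
            for action in reversed(self._undo):
                try:
                    action()
                except OSError:
                    pass  # best effort; fsck reports anything left behind
            raise
        finally:
            self._txn_depth = 0
            self._undo = []
        self.db.execute("COMMIT")

    def _register_undo(self, action: Callable[[], None]) -> None:
        if self._txn_depth > 0:
            self._undo.append(action)

    def fs_mkdir(self, path: Path) -> None:
        path.mkdir()
        self._register_undo(lambda: path.rmdir())

    def fs_write(self, path: Path, data: bytes) -> None:
        if path.exists():
            raise RepositoryError(f"refusing to overwrite {path}")
        path.write_bytes(data)
        self._register_undo(lambda: path.unlink())

    def fs_move(self, src: Path, dst: Path) -> None:
        src.rename(dst)
        self._register_undo(lambda: dst.rename(src))

    def fs_rmdir(self, path: Path) -> None:
        # capture nothing but the path; only valid for empty directories
        path.rmdir()
        self._register_undo(lambda: path.mkdir())

    def fs_unlink(self, path: Path) -> None:
        data = path.read_bytes()
        path.unlink()
        self._register_undo(lambda: path.write_bytes(data))

    # -- users and groups ----------------------------------------------

    def _user_row(self, row: sqlite3.Row) -> User:
        groups = tuple(
            r["group_id"] for r in self.db.execute(
                "SELECT group_id FROM group_members WHERE user_id = ? "
                "ORDER BY group_id", (row["id"],))
        )
        return User(id=row["id"], username=row["username"],
                    role=Role(row["role"]), group_ids=groups)

    def get_user(self, user_id: int) -> User:
        row = self.db.execute(
            "SELECT * FROM users WHERE id = ?", (user_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown user id {user_id}")
        return self._user_row(row)

    def find_user(self, username: str) -> User:
        row = self.db.execute(
            "SELECT * FROM users WHERE username = ?", (username,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown user {username!r}")
        return self._user_row(row)

    def list_users(self) -> list[User]:
        rows = self.db.execute("SELECT * FROM users ORDER BY id").fetchall()
        return [self._user_row(r) for r in rows]

    def get_group(self, group_id: int) -> Group:
        row = self.db.execute(
            "SELECT * FROM groups WHERE id = ?", (group_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown group id {group_id}")
        members = tuple(
            r["user_id"] for r in self.db.execute(
                "SELECT user_id FROM group_members WHERE group_id = ? "
                "ORDER BY user_id", (group_id,))
        )
        return Group(id=row["id"], name=row["name"], member_ids=members)

    def find_group(self, name: str) -> Group:
        row = self.db.execute(
            "SELECT id FROM groups WHERE name = ?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown group {name!r}")
        return self.get_group(row["id"])

    # -- projects -------------------------------------------------------

    def _project_row(self, row: sqlite3.Row) -> Project:
        return Project(
            id=row["id"], name=row["name"], acronym=row["acronym"],
            description=row["description"], parent_id=row["parent_id"],
            owner_id=row["owner_id"], template_id=row["template_id"],
            created_at=row["created_at"], dirname=row["dirname"],
            characteristic_values=json.loads(row["characteristics"]),
        )

    def get_project(self, project_id: int) -> Project:
        row = self.db.execute(
            "SELECT * FROM projects WHERE id = ?", (project_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown project id {project_id}")
        return self._project_row(row)

    def children(self, parent_id: int | None) -> list[Project]:
        if parent_id is None:
            rows = self.db.execute(
                "SELECT * FROM projects WHERE parent_id IS NULL "
                "ORDER BY name").fetchall()
        else:
            rows = self.db.execute(
                "SELECT * FROM projects WHERE parent_id = ? ORDER BY name",
                (parent_id,)).fetchall()
        return [self._project_row(r) for r in rows]

    def iter_projects(self) -> list[Project]:
        rows = self.db.execute("SELECT * FROM projects ORDER BY id").fetchall()
        return [self._project_row(r) for r in rows]

    def subtree_ids(self, project_id: int) -> list[int]:
        """Preorder list of project ids rooted at ``project_id``."""
        out: list[int] = []
        stack = [self.get_project(project_id)]
        while stack:
            p = stack.pop()
            out.append(p.id)
            stack.extend(reversed(self.children(p.id)))
        return out

    def project_dir(self, project: Project) -> Path:
        """Absolute mirrored directory of a project."""
        parts: list[str] = []
        node: Project | None = project
        while node is not None:
            parts.append(node.dirname)
            node = (self.get_project(node.parent_id)
                    if node.parent_id is not None else None)
        return self.root.joinpath(*reversed(parts))

    def unique_dirname(self, name: str, parent_id: int | None,
                       project_id: int) -> str:
        """Slug for a project directory; the id is appended when two sibling
        names collapse onto the same slug."""
        slug = slugify(name)
        siblings = self.db.execute(
            "SELECT dirname FROM projects WHERE parent_id IS ? AND id != ?",
            (parent_id, project_id)).fetchall()
        taken = {r["dirname"] for r in siblings}
        if slug in taken or slug == INTERNAL_DIR:
            slug = f"{slug}_{project_id}"
        return slug

    # -- managed files ---------------------------------------------------

    def _file_row(self, row: sqlite3.Row) -> ManagedFile:
        return ManagedFile(
            id=row["id"], project_id=row["project_id"],
            filename=row["filename"], size_bytes=row["size_bytes"],
            checksum=row["checksum"],
            annotation_values=json.loads(row["annotations"]),
        )

    def get_file(self, file_id: int) -> ManagedFile:
        row = self.db.execute(
            "SELECT * FROM files WHERE id = ?", (file_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown file id {file_id}")
        return self._file_row(row)

    def files_of(self, project_id: int) -> list[ManagedFile]:
        rows = self.db.execute(
            "SELECT * FROM files WHERE project_id = ? ORDER BY filename",
            (project_id,)).fetchall()
        return [self._file_row(r) for r in rows]

    def set_file_annotations(self, file_id: int, values: dict[str, str]) -> None:
        self.db.execute(
            "UPDATE files SET annotations = ? WHERE id = ?",
            (json.dumps(values, sort_keys=True), file_id))

    # -- templates --------------------------------------------------------

    def _defs_of(self, template_id: int, kind: str) -> tuple[FieldDef, ...]:
        rows = self.db.execute(
            "SELECT * FROM template_defs WHERE template_id = ? AND kind = ? "
            "ORDER BY position", (template_id, kind)).fetchall()
        return tuple(
            FieldDef(
                name=r["name"], description=r["description"],
                default_value=r["default_value"],
                value_list=(tuple(json.loads(r["value_list"]))
                            if r["value_list"] is not None else None),
                mandatory=bool(r["mandatory"]),
                experimental_question=bool(r["experimental_question"]),
            )
            for r in rows
        )

    def get_template(self, template_id: int) -> Template:
        row = self.db.execute(
            "SELECT * FROM templates WHERE id = ?", (template_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown template id {template_id}")
        return Template(
            id=row["id"], name=row["name"], owner_id=row["owner_id"],
            description=row["description"],
            keywords=tuple(json.loads(row["keywords"])),
            characteristic_defs=self._defs_of(row["id"], "characteristic"),
            annotation_defs=self._defs_of(row["id"], "annotation"),
            locked=bool(row["locked"]),
        )

    def find_template(self, name: str) -> Template:
        row = self.db.execute(
            "SELECT id FROM templates WHERE name = ?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown template {name!r}")
        return self.get_template(row["id"])

    def list_templates(self) -> list[Template]:
        rows = self.db.execute("SELECT id FROM templates ORDER BY id").fetchall()
        return [self.get_template(r["id"]) for r in rows]

    # -- grants -----------------------------------------------------------

    def grants_for(self, project_id: int) -> list[Grant]:
        rows = self.db.execute(
            "SELECT * FROM grants WHERE project_id = ? "
            "ORDER BY principal_kind, principal_id", (project_id,)).fetchall()
        return [
            Grant(project_id=r["project_id"], principal_kind=r["principal_kind"],
                  principal_id=r["principal_id"], level=GrantLevel(r["level"]))
            for r in rows
        ]

    def upsert_grant(self, project_id: int, principal_kind: str,
                     principal_id: int, level: GrantLevel) -> Grant:
        """Record a grant; an existing higher level wins over a lower one."""
        row = self.db.execute(
            "SELECT level FROM grants WHERE project_id = ? AND "
            "principal_kind = ? AND principal_id = ?",
            (project_id, principal_kind, principal_id)).fetchone()
        effective = level if row is None else GrantLevel(max(row["level"], level))
        self.db.execute(
            "INSERT INTO grants (project_id, principal_kind, principal_id, level) "
            "VALUES (?, ?, ?, ?) "
            "ON CONFLICT (project_id, principal_kind, principal_id) "
            "DO UPDATE SET level = excluded.level",
            (project_id, principal_kind, principal_id, int(effective)))
        return Grant(project_id, principal_kind, principal_id, effective)

    # -- snapshots ---------------------------------------------------------

    def list_snapshots(self, project_id: int | None = None) -> list[SnapshotRecord]:
        if project_id is None:
            rows = self.db.execute(
                "SELECT * FROM snapshots ORDER BY id").fetchall()
        else:
            rows = self.db.execute(
                "SELECT * FROM snapshots WHERE project_id = ? ORDER BY id",
                (project_id,)).fetchall()
        return [
            SnapshotRecord(
                id=r["id"], project_id=r["project_id"],
                created_at=r["created_at"], archive_path=r["archive_path"],
                manifest=tuple((p, c) for p, c in json.loads(r["manifest"])),
            )
            for r in rows
        ]

    def checksum(self, data: bytes) -> str:
        return checksum_bytes(data, self.config.get("checksum", "sha256"))


# ---------------------------------------------------------------------------
# archive ingestion


def _detect_format(path: Path) -> str:
    """Classify an input by magic bytes: zip, tar.gz, plain tar, or a
    single opaque file."""
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head[:4] == b"PK\x03\x04" or head[:4] == b"PK\x05\x06":
        return "zip"
    if head[:2] == b"\x1f\x8b":
        return "tar.gz"
    if tarfile.is_tarfile(path):
        return "tar"
    return "file"


def _extract_members(path: Path) -> list[tuple[str, bytes]]:
    """Flatten an archive (or a single file) to (basename, bytes) pairs.

    Directory structure inside archives is discarded — managed files live
    flat in their project directory — and a basename collision after
    flattening is an error.
    """
    fmt = _detect_format(path)
    members: list[tuple[str, bytes]] = []
    if fmt == "zip":
        try:
            with zipfile.ZipFile(path) as zf:
                for info in zf.infolist():
                    if info.is_dir():
                        continue
                    base = info.filename.rsplit("/", 1)[-1]
                    if not base:
                        continue
                    members.append((base, zf.read(info)))
        except zipfile.BadZipFile as exc:
            raise ArchiveError(f"corrupt zip archive: {path}") from exc
    elif fmt in ("tar", "tar.gz"):
        mode = "r:gz" if fmt == "tar.gz" else "r:"
        try:
            with tarfile.open(path, mode) as tf:
                for info in tf.getmembers():
                    if not info.isfile():
                        continue
                    base = info.name.rsplit("/", 1)[-1]
                    if not base:
                        continue
                    fh = tf.extractfile(info)
                    members.append((base, fh.read() if fh else b""))
        except tarfile.TarError as exc:
            raise ArchiveError(f"corrupt tar archive: {path}") from exc
    else:
        members.append((path.name, path.read_bytes()))
    seen: set[str] = set()
    for name, _ in members:
        if name in seen:
            raise ArchiveError(
                f"duplicate filename after flattening: {name!r}")
        seen.add(name)
    return members


def import_files(repo: Repository, project_id: int, source: str | Path,
                 actor: int) -> list[ManagedFile]:
    """Register the file, or every file of a zip/tar/tar.gz archive, into a
    project.

    Bytes are copied into the project's mirrored directory; size and
    checksum are recorded; when the project carries a template every new
    file starts from the template's effective annotation defaults.  The
    whole import is atomic: any error (unsupported archive, duplicate
    filename) adds zero files and leaves the directory unchanged.
    """
    from .permissions import can  # local import: permissions layer sits above

    project = repo.get_project(project_id)
    if not can(repo, actor, "edit", project):
        raise PermissionDeniedError(
            f"user {actor} may not edit project {project.name!r}")
    source = Path(source)
    if not source.exists():
        raise NotFoundError(f"no such file: {source}")
    members = _extract_members(source)
    if not members:
        raise ArchiveError(f"archive contains no regular files: {source}")

    existing = {f.filename for f in repo.files_of(project_id)}
    for name, _ in members:
        if name in existing:
            raise DuplicateNameError(
                f"file {name!r} already exists in project {project.name!r}; "
                "import rejected")

    defaults: dict[str, str] = {}
    if project.template_id is not None:
        tpl = repo.get_template(project.template_id)
        defaults = {d.name: d.effective_default() for d in tpl.annotation_defs}

    target_dir = repo.project_dir(project)
    created: list[ManagedFile] = []
    with repo.transaction():
        for name, data in members:
            cur = repo.db.execute(
                "INSERT INTO files (project_id, filename, size_bytes, checksum, "
                "annotations) VALUES (?, ?, ?, ?, ?)",
                (project_id, name, len(data), repo.checksum(data),
                 json.dumps(defaults, sort_keys=True)))
            repo.fs_write(target_dir / name, data)
            created.append(repo.get_file(cur.lastrowid))
    return created


# ---------------------------------------------------------------------------
# mirror verification


def mirror_check(repo: Repository, verify_checksums: bool = False) -> list[MirrorIssue]:
    """Two-way comparison of catalog and disk; empty list ⇔ consistent.

    Checks that every project has its mirrored directory, every managed
    file exists on disk (optionally with a matching checksum), and that no
    unregistered path sits inside the repository tree.
    """
    issues: list[MirrorIssue] = []
    expected_dirs: set[Path] = set()
    expected_files: set[Path] = set()

    for project in repo.iter_projects():
        pdir = repo.project_dir(project)
        expected_dirs.add(pdir)
        if not pdir.is_dir():
            issues.append(MirrorIssue(
                kind="missing_dir",
                path=str(pdir.relative_to(repo.root)),
                object_id=project.id))
            continue
        for mf in repo.files_of(project.id):
            fpath = pdir / mf.filename
            expected_files.add(fpath)
            if not fpath.is_file():
                issues.append(MirrorIssue(
                    kind="missing_file",
                    path=str(fpath.relative_to(repo.root)),
                    object_id=mf.id))
            elif verify_checksums:
                if repo.checksum(fpath.read_bytes()) != mf.checksum:
                    issues.append(MirrorIssue(
                        kind="checksum_mismatch",
                        path=str(fpath.relative_to(repo.root)),
                        object_id=mf.id))

    internal = repo.root / INTERNAL_DIR
    for path in sorted(repo.root.rglob("*")):
        if path == internal or internal in path.parents:
            continue
        if path.is_dir():
            if path not in expected_dirs:
                issues.append(MirrorIssue(
                    kind="orphan_path",
                    path=str(path.relative_to(repo.root))))
        elif path not in expected_files:
            issues.append(MirrorIssue(
                kind="orphan_path", path=str(path.relative_to(repo.root))))
    return issues


# ---------------------------------------------------------------------------
# snapshots (data freeze)


_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed member timestamps → diffable archives


def _zip_add(zf: zipfile.ZipFile, arcname: str, data: bytes) -> None:
    info = zipfile.ZipInfo(arcname, date_time=_ZIP_EPOCH)
    info.external_attr = 0o644 << 16
    zf.writestr(info, data, compress_type=zipfile.ZIP_STORED)


def snapshot(repo: Repository, project_id: int, actor: int) -> SnapshotRecord:
    """Freeze a project subtree into an immutable zip archive.

    The archive holds every managed file of the subtree (paths mirroring
    the sub-project structure), one exported annotation table per project
    (``annotation.txt``), and a ``manifest.json`` with the characteristics
    and template description of each project.  Member order and timestamps
    are fixed, so an unchanged project snapshots to a byte-identical
    archive.
    """
    from .annotations import export_table
    from .permissions import can

    project = repo.get_project(project_id)
    if not can(repo, actor, "read", project):
        raise PermissionDeniedError(
            f"user {actor} may not read project {project.name!r}")

    # (arcname, bytes) pairs; data files carry their stored checksum
    entries: list[tuple[str, bytes, str]] = []
    manifest_meta: dict = {"projects": []}

    def walk(pid: int, prefix: str) -> None:
        node = repo.get_project(pid)
        meta: dict = {
            "path": prefix.rstrip("/") or ".",
            "name": node.name,
            "description": node.description,
            "characteristics": dict(sorted(node.characteristic_values.items())),
        }
        if node.template_id is not None:
            tpl = repo.get_template(node.template_id)
            meta["template"] = {"name": tpl.name, "description": tpl.description}
        manifest_meta["projects"].append(meta)
        table = export_table(repo, pid, actor, _skip_permission=True)
        data = table.encode("utf-8")
        entries.append((prefix + "annotation.txt", data, repo.checksum(data)))
        pdir = repo.project_dir(node)
        for mf in repo.files_of(pid):
            entries.append(
                (prefix + mf.filename, (pdir / mf.filename).read_bytes(),
                 mf.checksum))
        for child in repo.children(pid):
            walk(child.id, prefix + child.dirname + "/")

    walk(project_id, "")
    manifest_bytes = json.dumps(
        manifest_meta, indent=2, sort_keys=True).encode("utf-8")
    entries.append(("manifest.json", manifest_bytes, repo.checksum(manifest_bytes)))
    entries.sort(key=lambda e: e[0])

    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        for arcname, data, _ in entries:
            _zip_add(zf, arcname, data)
    archive_bytes = buf.getvalue()

    manifest = [(arcname, digest) for arcname, _, digest in entries]
    created_at = utc_now()
    with repo.transaction():
        cur = repo.db.execute(
            "INSERT INTO snapshots (project_id, created_at, archive_path, manifest) "
            "VALUES (?, ?, '', ?)",
            (project_id, created_at, json.dumps(manifest)))
        snap_id = cur.lastrowid
        archive_path = (repo.root / INTERNAL_DIR / SNAPSHOT_DIR /
                        f"snapshot_{snap_id:04d}_{project.dirname}.zip")
        repo.db.execute("UPDATE snapshots SET archive_path = ? WHERE id = ?",
                        (str(archive_path), snap_id))
        repo.fs_write(archive_path, archive_bytes)
    return SnapshotRecord(
        id=snap_id, project_id=project_id, created_at=created_at,
        archive_path=str(archive_path), manifest=tuple(manifest))
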