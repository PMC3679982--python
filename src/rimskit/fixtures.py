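"""Deterministic synthetic study fixtures.

Builds everything the repository consumes — an archive of placeholder data
files, a matching annotation table, and a template definition — entirely
from a seed, so the full workflow can be exercised without any download.
Placeholder files are a few hundred seeded random bytes: the system treats
data files as opaque blobs, so their content is irrelevant.

Presets
-------
``worked_example_link``
    A breast-cancer transcriptome study schema: a template with five
    characteristics (Author, Original GEO/ArrayExpress Accession Number,
    Organism, Platform Vendor, Platform Type) and six clinical annotations,
    of which the distant-metastasis-free-survival variables ``e.dmfs`` and
    ``t.dmfs`` are flagged as experimental questions; plus a small archive
    and table to go with it.

``worked_example_import``
    A 198-sample microarray series: placeholder files
    ``sample_001.CEL`` ... ``sample_198.CEL``, a 198-row × 16-annotation
    clinical table (synthetic clinical-style variables, including
    ``e.dmfs``/``t.dmfs``), and the matching 16-definition template.  The
    16-column width is a reconstruction chosen so that a full first import
    updates 198 × 16 = 3168 annotation values.

``generic``
    ``n_files`` placeholder files and an ``n_files × annotation_columns``
    table with a matching blank template.
"""

from __future__ import annotations

import io
import random
import zipfile
from dataclasses import dataclass
from pathlib import Path

import yaml

CHARACTERISTICS_5 = (
    "Author",
    "Original GEO/ArrayExpress Accession Number",
    "Organism",
    "Platform Vendor",
    "Platform Type",
)

ANNOTATIONS_6 = ("id", "age", "grade", "er", "t.dmfs", "e.dmfs")

ANNOTATIONS_16 = (
    "id", "age", "size", "grade", "er", "node", "treatment", "histtype",
    "angioinv", "lymph_infil", "npi", "t.rfs", "e.rfs", "t.dmfs", "e.dmfs",
    "t.os",
)

EXPERIMENTAL_QUESTIONS = ("t.dmfs", "e.dmfs")

_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


@dataclass
class FixtureSpec:
    """What to generate; same (preset, seed) ⇒ byte-identical outputs."""

    root: Path
    preset: str = "generic"
    n_files: int = 3
    annotation_columns: int = 2
    seed: int = 0


@dataclass(frozen=True)
class FixturePaths:
    archive: Path
    table: Path
    template: Path


def _placeholder_archive(path: Path, filenames: list[str], rng: random.Random) -> None:
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        for name in filenames:
            info = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
            info.external_attr = 0o644 << 16
            zf.writestr(info, rng.randbytes(rng.randint(200, 400)),
                        compress_type=zipfile.ZIP_STORED)
    path.write_bytes(buf.getvalue())


def _clinical_value(column: str, rng: random.Random, sample_index: int) -> str:
    """Plausible, always-nonempty clinical-style token for one cell."""
    if column == "id":
        return f"P{sample_index + 1:03d}"
    if column == "age":
        return str(rng.randint(24, 72))
    if column == "size":
        return f"{rng.uniform(0.5, 5.0):.1f}"
    if column == "grade":
        return str(rng.randint(1, 3))
    if column in ("er", "node", "angioinv", "lymph_infil"):
        return str(rng.randint(0, 1))
    if column == "treatment":
        return rng.choice(["none", "chemo", "hormono"])
    if column == "histtype":
        return rng.choice(["ductal", "lobular", "mixed", "other"])
    if column == "npi":
        return f"{rng.uniform(2.0, 7.0):.2f}"
    if column.startswith("t."):  # follow-up time, days
        return str(rng.randint(120, 6000))
    if column.startswith("e."):  # event indicator
        return str(rng.randint(0, 1))
    return f"v{rng.randint(1, 9)}"


def _table_text(filenames: list[str], columns: tuple[str, ...] | list[str],
                rng: random.Random) -> str:
    lines = ["\t".join(["Filename", *columns])]
    for i, name in enumerate(filenames):
        cells = [_clinical_value(c, rng, i) for c in columns]
        lines.append("\t".join([name, *cells]))
    return "\n".join(lines) + "\n"


def _template_doc(name: str, keywords: list[str], description: str,
                  characteristics: tuple[str, ...] | list[str],
                  annotations: tuple[str, ...] | list[str]) -> dict:
    return {
        "name": name,
        "keywords": keywords,
        "description": description,
        "characteristics": [{"name": c} for c in characteristics],
        "annotations": [
            {"name": a, "experimental_question": True}
            if a in EXPERIMENTAL_QUESTIONS else {"name": a}
            for a in annotations
        ],
    }


def generate(spec: FixtureSpec) -> FixturePaths:
    """Write the fixture described by ``spec`` into ``spec.root`` and
    return the three generated paths (archive, annotation table, template
    definition)."""
    root = Path(spec.root)
    root.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    if spec.preset == "worked_example_link":
        filenames = [f"sample_{i + 1:03d}.CEL" for i in range(4)]
        columns = ANNOTATIONS_6
        doc = _template_doc(
            "Breast Cancer Transcriptome Template",
            ["Transcriptome", "Breast", "Cancer", "Clinical", "Data"],
            "Template for describing microarray of breast cancer samples",
            CHARACTERISTICS_5, ANNOTATIONS_6)
    elif spec.preset == "worked_example_import":
        filenames = [f"sample_{i + 1:03d}.CEL" for i in range(198)]
        columns = ANNOTATIONS_16
        doc = _template_doc(
            "Breast Cancer Clinical Import Template",
            ["Transcriptome", "Breast", "Cancer", "Clinical", "Data"],
            "Synthetic 16-variable clinical annotation schema for a "
            "198-sample microarray series",
            CHARACTERISTICS_5, ANNOTATIONS_16)
    elif spec.preset == "generic":
        filenames = [f"file_{i + 1:03d}.dat" for i in range(spec.n_files)]
        columns = tuple(f"var_{j + 1:02d}" for j in range(spec.annotation_columns))
        doc = _template_doc(
            f"Generic Template (seed {spec.seed})", ["synthetic"],
            "Synthetic schema for randomized testing",
            ("Organism", "Platform"), columns)
    else:
        raise ValueError(f"unknown preset {spec.preset!r}")

    paths = FixturePaths(
        archive=root / "files.zip",
        table=root / "annotation.txt",
        template=root / "template.yaml",
    )
    _placeholder_archive(paths.archive, filenames, rng)
    paths.table.write_text(_table_text(filenames, columns, rng),
                           encoding="utf-8")
    paths.template.write_text(yaml.safe_dump(doc, sort_keys=False),
                              encoding="utf-8")
    return paths
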