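"""Readers and writers for the external formats the pipeline touches.

Expression data travel as tab-separated text (genes as rows, samples as
columns), gene sets as GMT, sample annotations as TSV, reports as JSON and
histology images as 8-bit RGB PNG/TIFF.  All downstream modules operate only
on the in-memory types defined here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hccpipe")

TISSUE_CLASSES = ("cirrhosis", "tumor")
STAGES = ("T1", "T2", "T3", "TX", "NA")
PHENOTYPES = ("intra", "peri", "unknown")

TUMOR_STAGES = ("T1", "T2", "T3")


class FormatError(ValueError):
    """Malformed external input; message carries file coordinates."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``data`` is indexed by gene id with sample ids as columns; both id lists
    must be unique and the values non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if not np.issubdtype(self.data.values.dtype, np.integer):
            raise FormatError("count matrix values must be integers")
        if (self.data.values < 0).any():
            r, c = np.argwhere(self.data.values < 0)[0]
            raise FormatError(
                f"negative count at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of real expression values (log2 units)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample labels: tissue class, TNM stage, immune phenotype, cohort.

    Stage TX/NA samples are excluded from stage-association testing and
    phenotype-unknown samples from differential expression; those exclusions
    are applied by the consuming modules, not here.
    """

    data: pd.DataFrame  # index sample_id; columns tissue_class, stage, phenotype, cohort

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col, allowed in (
            ("tissue_class", TISSUE_CLASSES),
            ("stage", STAGES),
            ("phenotype", PHENOTYPES),
        ):
            bad = set(self.data[col]) - set(allowed)
            if bad:
                raise FormatError(f"unknown {col} value(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.data.loc[list(sample_ids)])

    def samples_with(self, **criteria: object) -> list[str]:
        """Sample ids matching all column==value (or value-in-list) criteria."""
        keep = pd.Series(True, index=self.data.index)
        for col, val in criteria.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                keep &= self.data[col].isin(list(val))
            else:
                keep &= self.data[col] == val
        return list(self.data.index[keep])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleAnnotation) and self.data.equals(other.data)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT contents)."""

    sets: Mapping[str, list[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and dict(self.sets) == dict(
            other.sets
        ) and dict(self.descriptions) == dict(other.descriptions)


def _check_unique(ids, kind: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Count / expression matrices (TSV)
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a gene x sample TSV of integer counts, preserving file order.

    First column holds gene ids, the header row sample ids.  Duplicate ids
    and non-integer or negative cells raise :class:`FormatError` with the
    offending coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    values = np.empty(df.shape, dtype=np.int64)
    for i, gene in enumerate(df.index):
        for j, sample in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at gene {gene!r}, "
                    f"sample {sample!r} (row {i + 2}, column {j + 2})"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at gene {gene!r}, sample {sample!r}"
                )
            values[i, j] = v
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "gene_id"
    return CountMatrix(out)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV of real-valued (log2) expression."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    df.index.name = "gene_id"
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(e: ExpressionMatrix, path: str | Path) -> None:
    df = e.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``.

    Duplicate genes within a set are dropped with a logged warning; a line
    with fewer than three fields is a format error carrying its line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene, got {len(fields)} field(s)"
                )
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s: line %d: set %r contains duplicate genes; de-duplicated",
                    path, lineno, name,
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in c.sets.items():
            desc = c.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Sample annotations (TSV)
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["sample_id", "tissue_class", "stage", "phenotype", "cohort"]


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV with the canonical five-column header.

    Missing stage is written "NA", missing phenotype "NA" or "unknown";
    tokens outside the enumerations (e.g. stage "T4") raise FormatError.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    df["phenotype"] = df["phenotype"].replace({"NA": "unknown", "": "unknown"})
    df["stage"] = df["stage"].replace({"": "NA"})
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.tissue_class not in TISSUE_CLASSES:
            raise FormatError(
                f"{path}: line {lineno}: unknown tissue class {row.tissue_class!r}"
            )
        if row.stage not in STAGES:
            raise FormatError(f"{path}: line {lineno}: unknown stage {row.stage!r}")
        if row.phenotype not in PHENOTYPES:
            raise FormatError(
                f"{path}: line {lineno}: unknown phenotype {row.phenotype!r}"
            )
    out = df.set_index("sample_id")[["tissue_class", "stage", "phenotype", "cohort"]]
    _check_unique(out.index, "sample")
    return SampleAnnotation(out)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    df = ann.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Reports (JSON) and images
# ---------------------------------------------------------------------------

def write_json_report(obj: object, path: str | Path) -> None:
    """Write a report as JSON with sorted keys (stable byte output)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as an 8-bit RGB array (H x W x 3)."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return np.asarray(arr, dtype=np.uint8)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8))
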