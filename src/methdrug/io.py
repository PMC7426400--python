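"""Readers, writers and identifier handling for the pipeline's external formats.

Every table the pipeline touches comes through here: omics matrices
(features x cell lines, delimited text with a header row of cell-line IDs),
long-form drug-response tables, BED interval files, and TF->target maps.
Loaders validate rather than coerce: a methylation beta outside [0,1] or a
non-binary mutation call is an error naming the offending entry, not a
silent clamp.

Coordinate conventions. Methylation tables key CpG islands by interval IDs
printed in the 1-based inclusive style ``"chr1: 110880394-110880624"``;
BED files are 0-based half-open per the standard. The conversion between
the two lives in :func:`parse_interval_id` / :func:`format_interval_id`
and nowhere else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "OmicsMatrix",
    "ResponseTable",
    "GenomicInterval",
    "ValidationError",
    "load_matrix",
    "write_matrix",
    "load_response",
    "write_response",
    "intersect_cells",
    "parse_interval_id",
    "format_interval_id",
    "load_bed",
    "write_bed",
    "load_tf_targets",
    "write_tf_targets",
]


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


class Modality(str, Enum):
    MUTATION = "mutation"
    COPY_NUMBER = "copy_number"
    EXPRESSION = "expression"
    METHYLATION = "methylation"
    DESCRIPTOR = "descriptor"


@dataclass
class OmicsMatrix:
    """A features x cell-lines value matrix with a modality tag.

    Invariants (enforced on construction): unique feature and cell IDs, no
    missing entries, mutation values in {0,1}, methylation values in [0,1].
    """

    modality: Modality
    feature_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # shape (n_features, n_cells), float64

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.cell_ids, "cell")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at feature {self.feature_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        if self.modality is Modality.MUTATION:
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-binary mutation value {self.values[i, j]!r} at gene "
                    f"{self.feature_ids[i]!r}, cell {self.cell_ids[j]!r}"
                )
        if self.modality is Modality.METHYLATION:
            bad = (self.values < 0.0) | (self.values > 1.0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"beta value {self.values[i, j]!r} outside [0,1] at CpG "
                    f"{self.feature_ids[i]!r}, cell {self.cell_ids[j]!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_ids)

    def subset_cells(self, cells: Sequence[str]) -> "OmicsMatrix":
        """Column-restrict to ``cells`` in the given order."""
        idx = {c: k for k, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in idx]
        if missing:
            raise ValidationError(f"unknown cell IDs: {missing[:5]}")
        cols = [idx[c] for c in cells]
        return OmicsMatrix(self.modality, list(self.feature_ids), list(cells), self.values[:, cols])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: Modality | str) -> "OmicsMatrix":
        return cls(Modality(modality), [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} ID {i!r}")
        seen.add(i)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_matrix(path: str | Path, modality: Modality | str) -> OmicsMatrix:
    """Load a delimited features x cells matrix (header row of cell IDs).

    The delimiter is sniffed from the extension (``.csv`` -> comma,
    anything else -> tab). Rows containing a missing value are dropped with
    a logged count (the missing-data policy: kernels and lasso require
    complete rows). Duplicate feature/cell IDs with identical values are
    deduplicated; conflicting duplicates are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no cell columns found (malformed header?)")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric entry ({exc})") from exc
    df = _dedupe(df, path, axis=0)
    df = _dedupe(df, path, axis=1)
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        log.info("%s: dropped %d feature rows with missing values", path, n_missing)
        df = df.dropna(axis=0)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no complete feature rows")
    return OmicsMatrix.from_frame(df, modality)


def _dedupe(df: pd.DataFrame, path: Path, axis: int) -> pd.DataFrame:
    labels = df.index if axis == 0 else df.columns
    if not labels.has_duplicates:
        return df
    what = "feature" if axis == 0 else "cell"
    dupes = labels[labels.duplicated()].unique()
    for d in dupes:
        block = df.loc[[d]] if axis == 0 else df.loc[:, [d]].T
        if not (block.fillna(np.inf).nunique(axis=0) <= 1).all():
            raise ValidationError(f"{path}: conflicting duplicate {what} ID {d!r}")
    keep = ~labels.duplicated()
    df = df.loc[keep] if axis == 0 else df.loc[:, keep]
    log.info("%s: deduplicated %d repeated %s IDs", path, len(dupes), what)
    return df


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path))


@dataclass
class ResponseTable:
    """Long-form (cell_id, drug_id, aucdr) records; AUCDR in [0,1]."""

    records: pd.DataFrame  # columns: cell_id, drug_id, aucdr

    def __post_init__(self) -> None:
        df = self.records
        required = ["cell_id", "drug_id", "aucdr"]
        if list(df.columns[:3]) != required:
            raise ValidationError(f"response table must have columns {required}, got {list(df.columns)}")
        df = df.copy()
        df["cell_id"] = df["cell_id"].astype(str).str.strip()
        df["drug_id"] = df["drug_id"].astype(str).str.strip()
        df["aucdr"] = df["aucdr"].astype(float)
        if df["aucdr"].isna().any():
            raise ValidationError("missing AUCDR value")
        bad = df[(df["aucdr"] < 0) | (df["aucdr"] > 1)]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"AUCDR {r.aucdr!r} outside [0,1] for pair ({r.cell_id!r}, {r.drug_id!r})"
            )
        if df.duplicated(["cell_id", "drug_id"]).any():
            r = df[df.duplicated(["cell_id", "drug_id"])].iloc[0]
            raise ValidationError(f"duplicate response for pair ({r.cell_id!r}, {r.drug_id!r})")
        self.records = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.records["cell_id"].unique())

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.records["drug_id"].unique())

    def subset_cells(self, cells: Iterable[str]) -> "ResponseTable":
        cells = set(cells)
        return ResponseTable(self.records[self.records["cell_id"].isin(cells)].reset_index(drop=True))


def load_response(path: str | Path) -> ResponseTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    return ResponseTable(df)


def write_response(table: ResponseTable, path: str | Path) -> None:
    path = Path(path)
    table.records.to_csv(path, sep=_sep_for(path), index=False)


def intersect_cells(
    matrices: Sequence[OmicsMatrix],
    responses: ResponseTable | None = None,
) -> tuple[list[OmicsMatrix], ResponseTable | None, dict[str, int]]:
    """Restrict all tables to their common cell-ID set, in sorted order.

    Returns the aligned matrices (identical cell ordering), the restricted
    response table (pairs whose cell survived), and a report of retained
    counts per modality. Raises on an empty intersection.
    """
    if not matrices:
        raise ValidationError("intersect_cells requires at least one matrix")
    common: set[str] = set(matrices[0].cell_ids)
    for m in matrices[1:]:
        common &= set(m.cell_ids)
    if responses is not None:
        common &= set(responses.records["cell_id"])
    if not common:
        raise ValidationError("no cell IDs shared by all inputs")
    ordered = sorted(common)
    report = {m.modality.value: len(ordered) for m in matrices}
    report["dropped_per_modality_max"] = max(m.n_cells - len(ordered) for m in matrices)
    aligned = [m.subset_cells(ordered) for m in matrices]
    out_resp = responses.subset_cells(ordered) if responses is not None else None
    for m in matrices:
        log.info("intersect_cells: %s retained %d/%d cells", m.modality.value, len(ordered), m.n_cells)
    return aligned, out_resp, report


# ---------------------------------------------------------------------------
# Genomic intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


_INTERVAL_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*(\d+)\s*-\s*(\d+)\s*$")


def parse_interval_id(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive interval ID like ``"chr1: 110880394-110880624"``.

    Returns the 0-based half-open equivalent: start = a-1, end = b.
    """
    m = _INTERVAL_RE.match(text)
    if not m:
        raise ValidationError(f"cannot parse interval ID {text!r} (expected 'chrom: a-b')")
    chrom, a, b = m.group(1), int(m.group(2)), int(m.group(3))
    if a < 1:
        raise ValidationError(f"interval ID {text!r}: 1-based start must be >= 1")
    if a > b:
        raise ValidationError(f"interval ID {text!r}: start exceeds end")
    return GenomicInterval(chrom, a - 1, b, name=text.strip())


def format_interval_id(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_interval_id` (1-based inclusive, spaced style)."""
    return f"{interval.chrom}: {interval.start + 1}-{interval.end}"


def load_bed(path: str | Path) -> list[GenomicInterval]:
    """Load a BED file (>=3 columns, 0-based half-open). Overlaps are kept as-is."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: expected >=3 tab-separated BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start {start} >= end {end}")
            intervals.append(GenomicInterval(chrom, start, end, name))
    if not intervals:
        raise ValidationError(f"{path}: empty BED file")
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t.\n")


def load_tf_targets(path: str | Path) -> dict[str, set[str]]:
    """Load a TF->target TSV (>=2 columns: TF, target; extras ignored).

    Duplicate (TF, target) rows collapse to set semantics.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: TF-target table needs >=2 columns")
    out: dict[str, set[str]] = {}
    for tf, target in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(tf).strip(), set()).add(str(target).strip())
    return out


def write_tf_targets(tf_targets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("TF\ttarget\tmode\n")
        for tf in sorted(tf_targets):
            for target in sorted(set(tf_targets[tf])):
                fh.write(f"{tf}\t{target}\tUnknown\n")
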