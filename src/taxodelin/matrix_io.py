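"""Reading, validation and writing of pairwise identity matrices and partitions.

An identity matrix holds one percent-identity value per genome pair (AAI,
ANI, dDDH or POCP).  One-way calculators can produce slightly asymmetric
tables (A→B vs B→A); on ingestion the two cells are averaged and a
discrepancy above 0.5 percentage points triggers a warning, because the
downstream clustering treats identity as a single pairwise value.  The
diagonal is definitional self-identity and is always coerced to 100.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np
import pandas as pd

PathOrStream = Union[str, Path, TextIO]

#: discrepancy (percentage points) between v_ij and v_ji above which a
#: warning is issued while symmetrizing
ASYMMETRY_WARN = 0.5

_METRICS = {"AAI", "ANI", "dDDH", "POCP", "other"}


class MatrixFormatError(ValueError):
    """Raised for malformed identity-matrix input."""


@dataclass
class IdentityMatrix:
    """Symmetric genome-by-genome percent-identity table.

    Parameters
    ----------
    genome_ids : list of str
        Unique genome identifiers, in matrix row order.
    values : (n, n) ndarray
        Percent identities in [0, 100], symmetric, diagonal 100. Values
        are stored rounded to 2 decimals, matching the 0.01 threshold
        granularity of the cut-off sweep.
    metric_label : str
        One of ``AAI``, ``ANI``, ``dDDH``, ``POCP``, ``other``.
    """

    genome_ids: list[str]
    values: np.ndarray
    metric_label: str = "other"

    def __post_init__(self) -> None:
        self.genome_ids = list(self.genome_ids)
        if len(set(self.genome_ids)) != len(self.genome_ids):
            dupes = sorted({g for g in self.genome_ids
                            if self.genome_ids.count(g) > 1})
            raise MatrixFormatError(f"duplicate genome ids: {dupes}")
        if self.metric_label not in _METRICS:
            raise MatrixFormatError(
                f"metric_label must be one of {sorted(_METRICS)}, "
                f"got {self.metric_label!r}")
        v = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if v.shape != (n, n):
            raise MatrixFormatError(
                f"values shape {v.shape} does not match {n} genome ids")
        self.values = symmetrize(v, self.genome_ids)

    @property
    def n(self) -> int:
        return len(self.genome_ids)

    def value(self, a: str, b: str) -> float:
        """Identity between genomes *a* and *b*."""
        return float(self.values[self._idx(a), self._idx(b)])

    def _idx(self, g: str) -> int:
        try:
            return self.genome_ids.index(g)
        except ValueError:
            raise KeyError(f"genome id {g!r} not in matrix") from None

    def off_diagonal(self) -> np.ndarray:
        """All off-diagonal values as a 1-D array (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids,
                            columns=self.genome_ids)

    def reordered(self, order: Sequence[str]) -> "IdentityMatrix":
        """Return a copy with genomes in the given order."""
        idx = [self._idx(g) for g in order]
        return IdentityMatrix(list(order), self.values[np.ix_(idx, idx)],
                              self.metric_label)


def symmetrize(values: np.ndarray, genome_ids: Sequence[str] | None = None,
               warn_above: float = ASYMMETRY_WARN) -> np.ndarray:
    """Average v_ij and v_ji, coerce the diagonal to 100, round to 2 dp.

    Idempotent: applying it twice gives the same matrix.  NaN cells stay
    NaN (missing), and a NaN paired with a finite mirror cell takes the
    finite value.
    """
    v = np.asarray(values, dtype=float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        finite = np.isfinite(v) & np.isfinite(v.T)
        disc = np.abs(v - v.T)
        if finite.any() and np.nanmax(np.where(finite, disc, 0)) > warn_above:
            i, j = np.unravel_index(
                np.argmax(np.where(finite, disc, 0)), v.shape)
            a = genome_ids[i] if genome_ids is not None else f"row {i}"
            b = genome_ids[j] if genome_ids is not None else f"row {j}"
            warnings.warn(
                f"asymmetric input: |v({a},{b}) - v({b},{a})| = "
                f"{disc[i, j]:.2f} > {warn_above} percentage points; "
                "cells averaged", stacklevel=2)
    sym = np.where(np.isnan(v), v.T, np.where(np.isnan(v.T), v, (v + v.T) / 2))
    np.fill_diagonal(sym, 100.0)
    off = sym[~np.eye(len(sym), dtype=bool)]
    bad = off[np.isfinite(off) & ((off < 0) | (off > 100))]
    if bad.size:
        raise MatrixFormatError(
            f"identity values outside [0, 100]: e.g. {bad[0]}")
    return np.round(sym, 2)


def _open(source: PathOrStream, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def _sniff_sep(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_matrix(source: PathOrStream, dialect: str = "square",
                metric_label: str = "other") -> IdentityMatrix:
    """Read a TSV/CSV identity matrix.

    Layout: first cell empty or ``id``, header row of genome ids, one
    labelled row per genome.  ``dialect='square'`` expects a full n×n
    body (asymmetric cells are averaged with a diagnostic);
    ``dialect='lower-triangle'`` expects row *i* to carry the values up
    to (and optionally including) the diagonal, and mirrors them.

    Raises
    ------
    MatrixFormatError
        On non-square square-dialect input, duplicate ids, or values
        outside [0, 100] (the offending row/column is named).
    """
    if dialect not in ("square", "lower-triangle"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, close = _open(source)
    try:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    finally:
        if close:
            fh.close()
    if not lines:
        raise MatrixFormatError("empty matrix file")
    sep = _sniff_sep(lines[0])
    header = lines[0].split(sep)
    if header and header[0].strip().lower() in ("", "id"):
        header = header[1:]
    col_ids = [h.strip() for h in header]
    rows: list[tuple[str, list[str]]] = []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(sep)]
        rows.append((parts[0], parts[1:]))
    row_ids = [r[0] for r in rows]
    n = len(rows)

    def parse(cell: str, rid: str, cid: str) -> float:
        if cell == "" or cell.upper() in ("NA", "NAN"):
            return np.nan
        try:
            x = float(cell)
        except ValueError:
            raise MatrixFormatError(
                f"non-numeric cell at row {rid!r}, column {cid!r}: "
                f"{cell!r}") from None
        if not 0.0 <= x <= 100.0:
            raise MatrixFormatError(
                f"value {x} outside [0, 100] at row {rid!r}, "
                f"column {cid!r}")
        return x

    if dialect == "square":
        if col_ids and col_ids != row_ids:
            raise MatrixFormatError(
                "square dialect: header ids and row ids differ")
        if any(len(cells) != n for _, cells in rows):
            raise MatrixFormatError(
                f"square dialect: expected {n} values per row")
        v = np.array([[parse(c, rid, row_ids[j])
                       for j, c in enumerate(cells)]
                      for rid, cells in rows])
    else:
        v = np.full((n, n), np.nan)
        for i, (rid, cells) in enumerate(rows):
            if len(cells) not in (i, i + 1):
                raise MatrixFormatError(
                    f"lower-triangle dialect: row {rid!r} has "
                    f"{len(cells)} values, expected {i} or {i + 1}")
            for j, c in enumerate(cells):
                v[i, j] = parse(c, rid, row_ids[j])
        v = np.where(np.isnan(v), v.T, v)
    return IdentityMatrix(row_ids, v, metric_label)


def write_matrix(matrix: IdentityMatrix, sink: PathOrStream,
                 sep: str = "\t") -> None:
    """Write a square TSV/CSV matrix with 2-decimal values."""
    fh, close = _open(sink, "w")
    try:
        fh.write(sep.join(["id"] + matrix.genome_ids) + "\n")
        for gid, row in zip(matrix.genome_ids, matrix.values):
            cells = ["" if np.isnan(x) else f"{x:.2f}" for x in row]
            fh.write(sep.join([gid] + cells) + "\n")
    finally:
        if close:
            fh.close()


@dataclass
class Partition:
    """Disjoint grouping of the full genome set.

    ``groups`` are non-empty, pairwise-disjoint sets of genome ids whose
    union is the genome set; ``threshold_used`` records the identity
    cut-off that produced it (NaN when not threshold-derived).
    """

    groups: list[frozenset[str]]
    threshold_used: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        self.groups = [frozenset(g) for g in self.groups]
        if not self.groups or any(not g for g in self.groups):
            raise ValueError("partition groups must be non-empty")
        all_ids = [g for grp in self.groups for g in grp]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("partition groups are not disjoint")

    @property
    def genome_ids(self) -> frozenset[str]:
        return frozenset().union(*self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, genome: str) -> frozenset[str]:
        for grp in self.groups:
            if genome in grp:
                return grp
        raise KeyError(genome)

    def labels(self, order: Sequence[str]) -> np.ndarray:
        """Integer group labels for genomes in the given order."""
        key = {g: i for i, grp in enumerate(self.sorted_groups())
               for g in grp}
        return np.array([key[g] for g in order])

    def sorted_groups(self) -> list[frozenset[str]]:
        """Groups by size descending, ties by lexicographic leader."""
        return sorted(self.groups, key=lambda g: (-len(g), min(g)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return set(self.groups) == set(other.groups)

    def __hash__(self) -> int:
        return hash(frozenset(self.groups))


def write_partition(partition: Partition, sink: PathOrStream) -> None:
    """Write a two-column TSV (genome_id, group_id).

    Ordering is deterministic: groups by size descending then
    lexicographic leader; members lexicographic within a group.
    """
    if not isinstance(partition, Partition) or not partition.groups:
        raise ValueError("empty or invalid partition")
    fh, close = _open(sink, "w")
    try:
        fh.write("genome_id\tgroup_id\n")
        for k, grp in enumerate(partition.sorted_groups(), start=1):
            for g in sorted(grp):
                fh.write(f"{g}\tG{k}\n")
    finally:
        if close:
            fh.close()


def read_partition(source: PathOrStream) -> Partition:
    """Read a two-column (genome_id, group_id) TSV back into a Partition."""
    fh, close = _open(source)
    try:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    finally:
        if close:
            fh.close()
    body = lines[1:] if lines and lines[0].startswith("genome_id") else lines
    by_group: dict[str, set[str]] = {}
    for ln in body:
        gid, grp = ln.split("\t")
        by_group.setdefault(grp, set()).add(gid)
    return Partition(list(by_group.values()))
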