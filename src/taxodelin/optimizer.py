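"""Monophyly-preserving identity threshold optimizer.

The genus cut-off search sweeps a candidate threshold over an AAI matrix
(default 60.00 → 80.00 in 0.01 steps).  At each threshold every genome
defines a neighborhood cluster — itself plus every genome at or above
the threshold — and identical clusters are deduplicated.  A clustering
in which some genome sits in several clusters violates operational
monophyly and is penalized heavily (more than the number of genomes per
extra membership), while singleton clusters draw a small deduction.
Maximal runs of thresholds with equal score form plateaus; the top
plateau, reported as center ± half-width, is the recommended cut-off.

Thresholds and identity values are handled on an integer centi-percent
grid (e.g. 63.43 → 6343) so that stepping by 0.01 is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from taxodelin.matrix_io import IdentityMatrix

EDGE_RULES = ("ge", "gt")


class IncompleteMatrixError(ValueError):
    """The sweep needs a complete matrix; missing cells are rejected."""


@dataclass
class PenaltyConfig:
    """Score deductions for monophyly violations and singletons.

    ``p_multi`` is charged once per *extra* cluster membership of a
    genome and must exceed the genome count, so that a single
    multi-membership outweighs any number of singleton deductions;
    ``p_single`` is charged per singleton cluster.
    """

    p_multi: int
    p_single: int
    n_genomes: int

    def __post_init__(self) -> None:
        if self.p_multi <= self.n_genomes:
            raise ValueError(
                f"p_multi ({self.p_multi}) must exceed the number of "
                f"genomes ({self.n_genomes})")
        if self.p_single < 1:
            raise ValueError("p_single must be >= 1")

    @classmethod
    def default(cls, n_genomes: int, p_single: int = 1) -> "PenaltyConfig":
        """Smallest integer penalties satisfying the ordering constraint."""
        return cls(p_multi=n_genomes + 1, p_single=p_single,
                   n_genomes=n_genomes)


@dataclass
class ClusterSet:
    """Deduplicated threshold neighborhoods, possibly overlapping."""

    threshold: float
    clusters: list[frozenset[str]]
    multi_members: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    @property
    def extra_memberships(self) -> int:
        return sum(m - 1 for m in self.multi_members.values())

    def is_partition(self) -> bool:
        """True when clusters are pairwise disjoint (monophyly holds)."""
        return all(m == 1 for m in self.multi_members.values())


@dataclass
class ThresholdScore:
    """Clustering quality at one grid threshold (score is <= 0)."""

    threshold: float
    score: int
    n_clusters: int
    n_multi_member_genomes: int
    n_singletons: int


@dataclass
class Plateau:
    """Maximal contiguous threshold run with a constant score."""

    t_low: float
    t_high: float
    score: int
    n_clusters: int

    @property
    def center(self) -> float:
        return round((self.t_low + self.t_high) / 2, 3)

    @property
    def half_width(self) -> float:
        return round((self.t_high - self.t_low) / 2, 3)

    def __contains__(self, t: float) -> bool:
        return self.t_low - 1e-9 <= t <= self.t_high + 1e-9

    def __str__(self) -> str:
        return f"{self.center:.2f} ± {self.half_width:.2f}"


def _centi(x: float) -> int:
    return int(round(x * 100))


def _adjacency(matrix: IdentityMatrix, t_centi: int,
               edge_rule: str) -> np.ndarray:
    v = np.round(matrix.values * 100).astype(np.int64)
    if edge_rule == "ge":
        adj = v >= t_centi
    elif edge_rule == "gt":
        adj = v > t_centi
    else:
        raise ValueError(f"edge_rule must be one of {EDGE_RULES}")
    np.fill_diagonal(adj, True)  # a genome always joins its own cluster
    return adj


def _check_complete(matrix: IdentityMatrix) -> None:
    if matrix.has_missing():
        raise IncompleteMatrixError(
            "matrix has missing cells; the threshold sweep requires a "
            "complete matrix")


def neighborhood_clusters(matrix: IdentityMatrix, t: float,
                          edge_rule: str = "ge") -> ClusterSet:
    """Cluster genomes by threshold neighborhoods at threshold *t*.

    Each genome g yields the candidate cluster {g} ∪ {h : v(g,h) ≥ t}
    (or strictly > under ``edge_rule='gt'``); identical sets are merged.
    ``multi_members`` counts, per genome, the deduplicated clusters
    containing it — any count above 1 marks a monophyly violation.
    """
    _check_complete(matrix)
    adj = _adjacency(matrix, _centi(t), edge_rule)
    ids = matrix.genome_ids
    uniq = {frozenset(np.compress(row, ids)) for row in adj}
    clusters = sorted(uniq, key=lambda c: (-len(c), sorted(c)))
    multi = {g: sum(1 for c in clusters if g in c) for g in ids}
    return ClusterSet(threshold=round(t, 2), clusters=clusters,
                      multi_members=multi)


def score_clustering(clusterset: ClusterSet,
                     penalties: PenaltyConfig) -> ThresholdScore:
    """Score a clustering: 0 iff a disjoint partition with no singletons.

    score = −(p_multi × Σ_g max(0, membership(g) − 1)
              + p_single × #singleton clusters)
    """
    extra = clusterset.extra_memberships
    n_single = clusterset.n_singletons
    score = -(penalties.p_multi * extra + penalties.p_single * n_single)
    n_multi = sum(1 for m in clusterset.multi_members.values() if m > 1)
    return ThresholdScore(threshold=clusterset.threshold, score=score,
                          n_clusters=clusterset.n_clusters,
                          n_multi_member_genomes=n_multi,
                          n_singletons=n_single)


def sweep(matrix: IdentityMatrix, t_min: float = 60.0, t_max: float = 80.0,
          step: float = 0.01, penalties: PenaltyConfig | None = None,
          edge_rule: str = "ge") -> list[ThresholdScore]:
    """Score every grid threshold from t_min to t_max inclusive.

    The default range covers 2001 grid points.  The implementation
    works on the integer centi-percent grid and vectorizes the cluster
    deduplication, so the full sweep on ~100 genomes takes seconds.
    """
    _check_complete(matrix)
    lo, hi, st = _centi(t_min), _centi(t_max), _centi(step)
    if not lo < hi:
        raise ValueError("t_min must be below t_max")
    if st < 1 or (hi - lo) % st != 0:
        raise ValueError("step must divide the range on the centi grid")
    if penalties is None:
        penalties = PenaltyConfig.default(matrix.n)
    v = np.round(matrix.values * 100).astype(np.int64)
    np.fill_diagonal(v, np.iinfo(np.int64).max)
    strict = edge_rule == "gt"
    if edge_rule not in EDGE_RULES:
        raise ValueError(f"edge_rule must be one of {EDGE_RULES}")
    out: list[ThresholdScore] = []
    for tc in range(lo, hi + 1, st):
        adj = (v > tc) if strict else (v >= tc)
        rows = np.unique(adj, axis=0)
        memberships = rows.sum(axis=0)          # clusters containing genome g
        sizes = rows.sum(axis=1)
        extra = int(memberships.sum()) - matrix.n
        n_single = int((sizes == 1).sum())
        score = -(penalties.p_multi * extra + penalties.p_single * n_single)
        out.append(ThresholdScore(
            threshold=tc / 100.0, score=score, n_clusters=len(rows),
            n_multi_member_genomes=int((memberships > 1).sum()),
            n_singletons=n_single))
    return out


def extract_plateaus(scan: Sequence[ThresholdScore]) -> list[Plateau]:
    """Collapse a scan into maximal equal-score runs, best first.

    Plateaus are ranked by score descending, ties broken by wider
    plateau first, then by lower center.  ``plateaus[0]`` is the
    recommended cut-off, reported as center ± half-width.
    """
    if not scan:
        raise ValueError("empty scan")
    plateaus: list[Plateau] = []
    start = 0
    for i in range(1, len(scan) + 1):
        if i == len(scan) or scan[i].score != scan[start].score:
            mid = scan[(start + i - 1) // 2]
            plateaus.append(Plateau(
                t_low=scan[start].threshold, t_high=scan[i - 1].threshold,
                score=scan[start].score, n_clusters=mid.n_clusters))
            start = i
    plateaus.sort(key=lambda p: (-p.score, -p.half_width, p.center))
    return plateaus


class ThresholdOptimizer(BaseEstimator):
    """Scikit-learn style wrapper around the threshold sweep.

    Parameters
    ----------
    t_min, t_max, step : float
        Sweep grid in percent; defaults 60.00–80.00 by 0.01.
    p_multi : int or "auto"
        Penalty per extra cluster membership; ``"auto"`` uses
        n_genomes + 1, the smallest value exceeding the genome count.
    p_single : int
        Penalty per singleton cluster.
    edge_rule : {"ge", "gt"}
        Whether a genome joins a neighborhood at identity equal to the
        threshold (inclusive, default) or only strictly above it.

    Attributes
    ----------
    scan_ : list of ThresholdScore
    plateaus_ : list of Plateau, best first
    best_plateau_ : Plateau
    best_threshold_ : float
        Center of the best plateau.

    Examples
    --------
    >>> from taxodelin import gen_identity_matrix, MatrixSpec
    >>> m, truth = gen_identity_matrix(MatrixSpec(group_sizes=[4, 3, 2],
    ...                                           seed=7))
    >>> opt = ThresholdOptimizer().fit(m)
    >>> opt.best_plateau_.score
    0
    """

    def __init__(self, t_min: float = 60.0, t_max: float = 80.0,
                 step: float = 0.01, p_multi: int | str = "auto",
                 p_single: int = 1, edge_rule: str = "ge"):
        self.t_min = t_min
        self.t_max = t_max
        self.step = step
        self.p_multi = p_multi
        self.p_single = p_single
        self.edge_rule = edge_rule

    def _as_matrix(self, X) -> IdentityMatrix:
        if isinstance(X, IdentityMatrix):
            return X
        X = np.asarray(X, dtype=float)
        ids = [f"g{i}" for i in range(len(X))]
        return IdentityMatrix(ids, X)

    def fit(self, X, y=None) -> "ThresholdOptimizer":
        """Run the sweep on an IdentityMatrix or square similarity array."""
        m = self._as_matrix(X)
        p_multi = m.n + 1 if self.p_multi == "auto" else int(self.p_multi)
        pen = PenaltyConfig(p_multi=p_multi, p_single=self.p_single,
                            n_genomes=m.n)
        self.penalties_ = pen
        self.scan_ = sweep(m, self.t_min, self.t_max, self.step, pen,
                           self.edge_rule)
        self.plateaus_ = extract_plateaus(self.scan_)
        self.best_plateau_ = self.plateaus_[0]
        self.best_threshold_ = self.best_plateau_.center
        self.n_features_in_ = m.n
        return self
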