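"""Genus and species delineation rules.

Genus: apply the chosen AAI cut-off; the threshold neighborhoods must
form a disjoint partition (operational monophyly), otherwise the cut is
rejected with a report of the offending genomes.

Species: two genomes are conspecific only when ANI ≥ ani_cut *and*
dDDH ≥ ddh_cut — if either index falls under its cut-off the pair is
called different species.  Species groups are the connected components
of the pairwise same-species graph; because the rule is applied
pairwise, non-transitive triples (A~B, B~C, A≁C) are possible and are
reported as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from taxodelin.matrix_io import IdentityMatrix, Partition
from taxodelin.optimizer import neighborhood_clusters


class MultiMembershipError(ValueError):
    """The genus cut-off places some genome in more than one cluster."""

    def __init__(self, offenders: dict[str, int], threshold: float):
        self.offenders = offenders
        self.threshold = threshold
        detail = ", ".join(f"{g} ({k} clusters)"
                           for g, k in sorted(offenders.items()))
        super().__init__(
            f"cut-off {threshold} violates monophyly; genomes in "
            f"multiple clusters: {detail}")


@dataclass
class CutoffConfig:
    """Delineation cut-offs in percent.

    ani_cut defaults to 95 with a 95–96 guidance band: pairs whose ANI
    falls inside [95, 96) are flagged borderline when band mode is on.
    """

    genus_aai_cut: float = 63.43
    ani_cut: float = 95.0
    ddh_cut: float = 70.0
    ani_band_high: float = 96.0

    def __post_init__(self) -> None:
        for name in ("genus_aai_cut", "ani_cut", "ddh_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must be in (0, 100), got {v}")


@dataclass
class SpeciesCall:
    """Pairwise same/different-species decision under the joint rule."""

    genome_a: str
    genome_b: str
    ani: float
    ddh: float
    same_species: bool
    failing_criteria: frozenset[str] = field(default_factory=frozenset)
    borderline: bool = False


def delineate_genera(matrix: IdentityMatrix, cut: float,
                     edge_rule: str = "ge") -> Partition:
    """Partition genomes into genera at the given identity cut-off.

    Raises :class:`MultiMembershipError` when any genome falls in more
    than one threshold neighborhood (the cut violates monophyly).
    """
    cs = neighborhood_clusters(matrix, cut, edge_rule)
    offenders = {g: m for g, m in cs.multi_members.items() if m > 1}
    if offenders:
        raise MultiMembershipError(offenders, cut)
    return Partition(groups=list(cs.clusters), threshold_used=round(cut, 2),
                     label=f"{matrix.metric_label}>={cut}")


def call_species(ani: IdentityMatrix, ddh: IdentityMatrix,
                 cut: CutoffConfig | None = None,
                 band_mode: bool = True,
                 ) -> tuple[list[SpeciesCall], Partition]:
    """Apply the joint ANI + dDDH rule to every genome pair.

    Returns one :class:`SpeciesCall` per unordered pair and the species
    :class:`Partition` (connected components of the same-species
    graph).  A warning is emitted for non-transitive triples.
    """
    if cut is None:
        cut = CutoffConfig()
    if set(ani.genome_ids) != set(ddh.genome_ids):
        raise ValueError("ANI and dDDH matrices cover different genome sets")
    ids = ani.genome_ids
    ddh = ddh.reordered(ids)
    n = len(ids)
    calls: list[SpeciesCall] = []
    same = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            a, d = ani.values[i, j], ddh.values[i, j]
            failing = set()
            if a < cut.ani_cut:
                failing.add("ANI")
            if d < cut.ddh_cut:
                failing.add("dDDH")
            is_same = not failing
            same[i, j] = same[j, i] = is_same
            calls.append(SpeciesCall(
                genome_a=ids[i], genome_b=ids[j], ani=a, ddh=d,
                same_species=is_same, failing_criteria=frozenset(failing),
                borderline=band_mode and cut.ani_cut <= a < cut.ani_band_high))
    n_comp, labels = connected_components(csr_matrix(same), directed=False)
    groups = [frozenset(ids[k] for k in np.flatnonzero(labels == c))
              for c in range(n_comp)]
    _warn_non_transitive(same, ids, labels)
    part = Partition(groups=groups, label="species")
    return calls, part


def _warn_non_transitive(same: np.ndarray, ids: list[str],
                         labels: np.ndarray) -> None:
    n = len(ids)
    bad: list[tuple[str, str, str]] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        for i in members:
            for j in members:
                if j <= i or same[i, j]:
                    continue
                # i and j share a component but are not called conspecific
                mid = next((k for k in members if same[i, k] and same[k, j]),
                           None)
                if mid is not None:
                    bad.append((ids[i], ids[mid], ids[j]))
    if bad:
        a, b, c = bad[0]
        warnings.warn(
            f"species rule is non-transitive for {len(bad)} triple(s), "
            f"e.g. {a}~{b} and {b}~{c} but not {a}~{c}; groups are "
            "connected components", stacklevel=3)


class GenusClusterer(BaseEstimator, ClusterMixin):
    """Scikit-learn style genus delineation at a fixed identity cut-off.

    ``fit`` accepts an :class:`IdentityMatrix` or a square similarity
    array and exposes integer ``labels_`` plus the ``partition_``.
    Raises :class:`MultiMembershipError` when the cut-off violates
    monophyly.
    """

    def __init__(self, cut: float = 63.43, edge_rule: str = "ge"):
        self.cut = cut
        self.edge_rule = edge_rule

    def fit(self, X, y=None) -> "GenusClusterer":
        if not isinstance(X, IdentityMatrix):
            X = IdentityMatrix([f"g{i}" for i in range(len(X))],
                               np.asarray(X, dtype=float))
        self.partition_ = delineate_genera(X, self.cut, self.edge_rule)
        self.genome_ids_ = list(X.genome_ids)
        self.labels_ = self.partition_.labels(self.genome_ids_)
        self.n_clusters_ = self.partition_.n_groups
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
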