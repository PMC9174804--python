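"""Codon-usage validation: ORF finding, RSCU, PCA, 3-D distances, ANOSIM.

Open reading frames are ATG-initiated and stop-terminated under the
bacterial genetic code (translation table 11).  Relative synonymous
codon usage is computed over the 59 informative codons — Met (ATG) and
Trp (TGG) are single-codon families and the three stop codons encode no
amino acid, so all five are excluded.  For codon c in a synonymous
family of size k,

    RSCU(c) = count(c) × k / Σ_{c' in family} count(c'),

so RSCU sums to k within each family with nonzero usage and averages 1.
Genome RSCU profiles are embedded by mean-centered PCA; pairwise
distances between genomes are Euclidean on the first three components;
and group separation is tested with ANOSIM, a rank-based permutation
test on the pairwise dissimilarities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

_TABLE11 = unambiguous_dna_by_id[11]
STOP_CODONS = tuple(sorted(_TABLE11.stop_codons))         # TAA, TAG, TGA
ALL_CODONS = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))

#: codon → amino acid for the 61 sense codons of table 11
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)

#: amino acid → synonymous codons (table 11), all 20 amino acids
AA_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in sorted(set(CODON_TO_AA.values()))
}

#: the 59 codons entering RSCU (Met, Trp and stops excluded), fixed order
RSCU_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS
    if c in CODON_TO_AA and CODON_TO_AA[c] not in ("M", "W"))

START_CODON = "ATG"


@dataclass(frozen=True)
class Orf:
    """One open reading frame in forward 0-based half-open coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: str           # '+' or '-'
    frame: int            # 0..2 on the reported strand
    n_codons: int         # ATG through stop, inclusive

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class CodonCounts:
    """64-codon tally over a genome's ORFs."""

    genome_id: str
    counts: dict[str, int]
    n_orfs: int = 0
    n_skipped_ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RscuProfile:
    """Per-genome RSCU vector over the 59 informative codons.

    Families with zero total usage get all-zero RSCU and are recorded
    in ``zero_families`` (dropping them would break the fixed 59-length
    vector the PCA needs).
    """

    genome_id: str
    rscu: dict[str, float]
    zero_families: frozenset[str] = frozenset()

    def as_vector(self) -> np.ndarray:
        return np.array([self.rscu[c] for c in RSCU_CODONS])


@dataclass
class Embedding:
    """PCA coordinates of genome RSCU profiles."""

    genome_ids: list[str]
    coordinates: np.ndarray            # (n, k)
    explained_variance_ratio: np.ndarray

    def coords_of(self, genome_id: str) -> np.ndarray:
        try:
            return self.coordinates[self.genome_ids.index(genome_id)]
        except ValueError:
            raise KeyError(f"genome id {genome_id!r} not in embedding"
                           ) from None


@dataclass
class AnosimResult:
    """ANOSIM R statistic and permutation p-value."""

    r_statistic: float
    p_value: float
    n_permutations: int
    dissimilarity_metric: str
    seed: int | None = None
    exact: bool = False


def _validate_sequence(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return s


def _scan_frame(seq: str, frame: int, min_codons: int
                ) -> list[tuple[int, int]]:
    """Maximal ATG→stop spans (5'-most ATG per stop) in one frame."""
    spans = []
    atg: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos:pos + 3]
        if "N" in codon:
            continue  # ambiguous: neither start nor stop
        if codon in STOP_CODONS:
            if atg is not None:
                end = pos + 3
                if (end - atg) // 3 >= min_codons:
                    spans.append((atg, end))
            atg = None
        elif codon == START_CODON and atg is None:
            atg = pos
    return spans


def find_orfs(sequence: str, min_codons: int = 50,
              strands: str = "both", sequence_id: str = "seq") -> list[Orf]:
    """Find ATG-initiated, stop-terminated ORFs of ≥ min_codons codons.

    Only the longest ORF per (frame, stop) is reported: its start is
    the 5'-most ATG after the previous in-frame stop, which avoids
    double-counting codons of nested ORFs.  Reverse-strand ORFs are
    reported in forward coordinates with ``strand='-'``.

    The codon count includes both the ATG and the stop codon, so
    ``ATGAAATAA`` is a 3-codon ORF.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    s = _validate_sequence(sequence)
    n = len(s)
    orfs: list[Orf] = []
    for frame in range(3):
        for a, b in _scan_frame(s, frame, min_codons):
            orfs.append(Orf(sequence_id, a, b, "+", frame, (b - a) // 3))
    if strands == "both":
        rc = str(Seq(s).reverse_complement())
        for frame in range(3):
            for a, b in _scan_frame(rc, frame, min_codons):
                orfs.append(Orf(sequence_id, n - b, n - a, "-", frame,
                                (b - a) // 3))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orf_codons(orf: Orf, sequence: str) -> list[str]:
    """Codons of an ORF, read 5'→3' on the ORF's own strand."""
    s = _validate_sequence(sequence)[orf.start:orf.end]
    if orf.strand == "-":
        s = str(Seq(s).reverse_complement())
    if len(s) != 3 * orf.n_codons:
        raise ValueError(
            f"ORF {orf.sequence_id}:{orf.start}-{orf.end} does not match "
            "its sequence (frame violation)")
    return [s[i:i + 3] for i in range(0, len(s), 3)]


def count_codons(orfs: Iterable[Orf], sequences: Mapping[str, str] | str,
                 genome_id: str = "genome") -> CodonCounts:
    """Tally all 64 codons over a set of ORFs.

    ``sequences`` maps sequence ids to nucleotide strings (a bare
    string is accepted for single-sequence input).  Codons containing
    N are skipped and counted in ``n_skipped_ambiguous``.
    """
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    n_orfs = 0
    for orf in orfs:
        seq = sequences if isinstance(sequences, str) \
            else sequences[orf.sequence_id]
        n_orfs += 1
        for codon in orf_codons(orf, seq):
            if "N" in codon:
                skipped += 1
                continue
            counts[codon] += 1
    if skipped:
        warnings.warn(f"{skipped} codon(s) containing N skipped",
                      stacklevel=2)
    return CodonCounts(genome_id=genome_id, counts=counts, n_orfs=n_orfs,
                       n_skipped_ambiguous=skipped)


def count_codons_cds(genome_id: str, cds_list: Sequence[str]) -> CodonCounts:
    """Tally codons of pre-extracted CDS directly (no ORF scanning)."""
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for k, s in enumerate(cds_list):
        s = _validate_sequence(s)
        if len(s) % 3:
            raise ValueError(
                f"CDS {k} of {genome_id} has length {len(s)}, "
                "not divisible by 3")
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            if "N" in codon:
                skipped += 1
                continue
            counts[codon] += 1
    if skipped:
        warnings.warn(f"{skipped} codon(s) containing N skipped",
                      stacklevel=2)
    return CodonCounts(genome_id=genome_id, counts=counts,
                       n_orfs=len(cds_list), n_skipped_ambiguous=skipped)


def profile_genome(genome_id: str, sequences: Mapping[str, str] | str,
                   min_codons: int = 50, strands: str = "both"
                   ) -> RscuProfile:
    """ORF-find, codon-count and RSCU a genome in one call."""
    seqs = {genome_id: sequences} if isinstance(sequences, str) \
        else dict(sequences)
    orfs = [o for sid, s in seqs.items()
            for o in find_orfs(s, min_codons, strands, sequence_id=sid)]
    return rscu(count_codons(orfs, seqs, genome_id=genome_id))


def profiles_from_cds(cds: Mapping[str, Sequence[str]]
                      ) -> list[RscuProfile]:
    """RSCU profiles for a per-genome CDS mapping."""
    return [rscu(count_codons_cds(gid, lst)) for gid, lst in cds.items()]


def rscu(counts: CodonCounts) -> RscuProfile:
    """RSCU over the 59 informative codons of translation table 11."""
    if counts.total == 0:
        raise ValueError(f"genome {counts.genome_id}: all-zero codon counts")
    values: dict[str, float] = {}
    zero: set[str] = set()
    for aa, family in AA_FAMILIES.items():
        if aa in ("M", "W"):
            continue
        k = len(family)
        tot = sum(counts.counts[c] for c in family)
        for c in family:
            values[c] = counts.counts[c] * k / tot if tot else 0.0
        if tot == 0:
            zero.add(aa)
    return RscuProfile(genome_id=counts.genome_id, rscu=values,
                       zero_families=frozenset(zero))


def profiles_to_matrix(profiles: Sequence[RscuProfile]
                       ) -> tuple[list[str], np.ndarray]:
    ids = [p.genome_id for p in profiles]
    return ids, np.vstack([p.as_vector() for p in profiles])


def pca_embed(profiles: Sequence[RscuProfile], k: int = 3) -> Embedding:
    """Mean-centered (unscaled) PCA of RSCU profiles.

    Sign convention: within each component, the loading of largest
    magnitude is made positive, so the embedding is deterministic.
    """
    ids, X = profiles_to_matrix(profiles)
    n = len(ids)
    if n < 2:
        raise ValueError("PCA needs at least 2 profiles")
    if not 1 <= k <= min(n - 1, X.shape[1]):
        raise ValueError(f"k must be in [1, {min(n - 1, X.shape[1])}]")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("all RSCU columns are constant; nothing to embed")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    flip = np.where(
        pca.components_[np.arange(k),
                        np.abs(pca.components_).argmax(axis=1)] < 0, -1.0, 1.0)
    return Embedding(genome_ids=ids, coordinates=coords * flip,
                     explained_variance_ratio=pca.explained_variance_ratio_)


def distance3d(embedding: Embedding, a: str, b: str) -> float:
    """Euclidean distance between two genomes on the first 3 components."""
    if embedding.coordinates.shape[1] < 3:
        raise ValueError("embedding has fewer than 3 components")
    pa, pb = embedding.coords_of(a)[:3], embedding.coords_of(b)[:3]
    return float(np.sqrt(((pa - pb) ** 2).sum()))


def group_distance_stats(embedding: Embedding, members: Sequence[str],
                         reference: str | None = None
                         ) -> tuple[float, float]:
    """Mean ± sd of 3-D distances within a group, or from a reference.

    With ``reference`` None, all unordered pairs among ``members`` are
    used; otherwise the distances from ``reference`` to each member.
    """
    if reference is None:
        d = [distance3d(embedding, x, y)
             for x, y in itertools.combinations(members, 2)]
    else:
        d = [distance3d(embedding, reference, m) for m in members]
    return float(np.mean(d)), float(np.std(d))


def _anosim_r(rank_sq: np.ndarray, labels: np.ndarray,
              iu: tuple[np.ndarray, np.ndarray]) -> float:
    ranks = rank_sq[iu]
    within = labels[iu[0]] == labels[iu[1]]
    m = ranks.size
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


def anosim(data, grouping: Mapping[str, str] | Sequence,
           n_permutations: int = 9999, metric: str = "braycurtis",
           seed: int | None = None, exact: bool = False) -> AnosimResult:
    """Analysis of similarities on RSCU profiles or dissimilarities.

    ``data`` may be a sequence of :class:`RscuProfile`, an (n, p)
    feature array, or (with ``metric='precomputed'``) a square
    dissimilarity matrix.  ``grouping`` maps genome id → group for
    profiles, or is a length-n label sequence for arrays.

    R = (mean between-group rank − mean within-group rank) / (M/2)
    over the ranks of all M = n(n−1)/2 pairwise dissimilarities; the
    permutation p-value carries the +1 correction.  With
    ``exact=True`` every distinct label arrangement is enumerated
    instead of sampling (feasible for small n) and p is the exact
    fraction of arrangements with R ≥ observed.
    """
    if (isinstance(data, Sequence) and len(data) > 0
            and isinstance(data[0], RscuProfile)):
        ids, X = profiles_to_matrix(data)
        labels_list = [grouping[g] for g in ids]
        dist = squareform(pdist(X, metric=metric))
    else:
        X = np.asarray(data, dtype=float)
        labels_list = list(grouping)
        if metric == "precomputed":
            if X.shape[0] != X.shape[1] or not np.allclose(X, X.T):
                raise ValueError("precomputed matrix must be square "
                                 "and symmetric")
            dist = X
        else:
            dist = squareform(pdist(X, metric=metric))
    n = dist.shape[0]
    if len(labels_list) != n:
        raise ValueError("grouping length does not match data")
    uniq = sorted(set(labels_list))
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    labels = np.array([uniq.index(g) for g in labels_list])
    if all(np.sum(labels == g) == 1 for g in range(len(uniq))):
        raise ValueError("all groups are singletons; no within-group pairs")
    iu = np.triu_indices(n, k=1)
    rank_sq = np.zeros_like(dist)
    rank_sq[iu] = rankdata(dist[iu])
    rank_sq += rank_sq.T
    r_obs = _anosim_r(rank_sq, labels, iu)

    if exact:
        arrangements = sorted({p for p in
                               itertools.permutations(labels.tolist())})
        r_perm = np.array([_anosim_r(rank_sq, np.array(p), iu)
                           for p in arrangements])
        p = float(np.mean(r_perm >= r_obs - 1e-12))
        return AnosimResult(r_statistic=float(r_obs), p_value=p,
                            n_permutations=len(arrangements),
                            dissimilarity_metric=metric, seed=seed,
                            exact=True)
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(rank_sq, perm, iu) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r_statistic=float(r_obs), p_value=float(p),
                        n_permutations=n_permutations,
                        dissimilarity_metric=metric, seed=seed)
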