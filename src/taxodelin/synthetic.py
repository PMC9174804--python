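"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* block-structured identity matrices with planted genera — within-group
  and between-group identities drawn from two normal distributions
  straddling a cut-off, plus optional "bridge" genomes wired into two
  groups to manufacture multi-cluster membership;
* coding sequences with group-specific codon-usage bias — per-group
  codon frequencies drawn from a Dirichlet per synonymous family, with
  a concentration-style ``bias_strength`` knob (0 means all groups share
  uniform usage);
* protein hit tables with planted pass/fail labels, including records
  placed exactly on filter boundaries to exercise strict vs inclusive
  modes.

Every generator is a pure function of its spec and seed, and always
returns the planted truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from taxodelin.matrix_io import IdentityMatrix, Partition, PathOrStream, _open
from taxodelin.protein_hits import FilterPreset, HitRecord, POCP_PRESET, \
    PocpInputs
from taxodelin.codon_usage import AA_FAMILIES, START_CODON, STOP_CODONS


@dataclass
class MatrixSpec:
    """Planted-genus identity matrix parameters (percent units).

    Defaults place within-group identity at 78 ± 1 and between-group at
    58 ± 1 — a wide gap around typical genus-level cut-offs, so the
    planted partition is recoverable at any threshold inside the gap.
    """

    group_sizes: Sequence[int] = (4, 3, 2)
    within_mean: float = 78.0
    within_sd: float = 1.0
    between_mean: float = 58.0
    between_sd: float = 1.0
    n_bridge_genomes: int = 0
    clamp: tuple[float, float] = (0.0, 100.0)
    seed: int = 0
    guarantee_gap: bool = True

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.guarantee_gap and not self.within_mean > self.between_mean:
            raise ValueError("within_mean must exceed between_mean")


@dataclass
class CodonBiasSpec:
    """Group-biased CDS generator parameters.

    ``bias_strength`` controls how far each group's per-family codon
    frequencies may drift from uniform: 0 pins every group to uniform
    usage (the null), larger values draw frequencies from a Dirichlet
    with concentration 1/bias_strength, so large values give extreme,
    nearly one-codon-per-family bias.
    """

    group_sizes: Sequence[int] = (5, 5, 5)
    orfs_per_genome: int = 40
    orf_length_codons: tuple[float, float] = (200.0, 50.0)  # mean, sd
    min_codons: int = 50
    bias_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.orf_length_codons[0] < self.min_codons:
            raise ValueError("mean ORF length below the minimum")


def gen_identity_matrix(spec: MatrixSpec
                        ) -> tuple[IdentityMatrix, Partition]:
    """Generate a symmetric planted-genus matrix and its true partition.

    Bridge genomes are appended after the regular groups; bridge *b* is
    wired with within-level identity into two host groups (cycling
    through consecutive group pairs), which creates the overlapping
    neighborhoods the optimizer penalizes.  In the returned truth,
    bridges are assigned to their first host group.

    Raises when ``guarantee_gap`` is set and the realized draws (after
    clamping) fail to keep every within-group identity above every
    between-group identity.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = list(spec.group_sizes)
    n_groups = len(sizes)
    if spec.n_bridge_genomes and n_groups < 2:
        raise ValueError("bridge genomes need at least 2 groups")
    ids: list[str] = []
    group_of: dict[str, int] = {}
    for gi, size in enumerate(sizes):
        for j in range(size):
            gid = f"grp{gi + 1:02d}_{j + 1:02d}"
            ids.append(gid)
            group_of[gid] = gi
    hosts: dict[str, tuple[int, int]] = {}
    for b in range(spec.n_bridge_genomes):
        gid = f"bridge{b + 1:02d}"
        ids.append(gid)
        hosts[gid] = (b % n_groups, (b + 1) % n_groups)
        group_of[gid] = hosts[gid][0]
    n = len(ids)
    lo, hi = spec.clamp

    def draw(mean: float, sd: float) -> float:
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    v = np.full((n, n), 100.0)
    within_vals, between_vals = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            ga = hosts.get(a, (group_of[a],))
            gb = hosts.get(b, (group_of[b],))
            within = bool(set(ga) & set(gb))
            x = draw(spec.within_mean if within else spec.between_mean,
                     spec.within_sd if within else spec.between_sd)
            (within_vals if within else between_vals).append(x)
            v[i, j] = v[j, i] = x
    if spec.guarantee_gap and within_vals and between_vals \
            and min(within_vals) <= max(between_vals):
        raise ValueError(
            "realized within/between identity distributions overlap "
            f"(min within {min(within_vals):.2f} <= max between "
            f"{max(between_vals):.2f}); widen the gap or disable "
            "guarantee_gap")
    matrix = IdentityMatrix(ids, v, metric_label="AAI")
    groups = [frozenset(g for g in ids if group_of[g] == gi)
              for gi in range(n_groups)]
    truth = Partition(groups=[g for g in groups if g], label="planted")
    return matrix, truth


def _family_frequencies(rng: np.random.Generator, bias_strength: float
                        ) -> dict[str, np.ndarray]:
    """Per-family codon frequencies for one group."""
    freqs = {}
    for aa, family in AA_FAMILIES.items():
        k = len(family)
        if bias_strength == 0 or k == 1:
            freqs[aa] = np.full(k, 1.0 / k)
        else:
            freqs[aa] = rng.dirichlet(np.full(k, 1.0 / bias_strength))
    return freqs


def gen_codon_fasta(spec: CodonBiasSpec
                    ) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Generate per-genome CDS with group-specific codon bias.

    Returns ``(cds, groups)``: ``cds`` maps genome id to its list of
    CDS strings (each ATG…stop, no internal stop, length divisible by
    3) and ``groups`` maps genome id to its group label.  Amino acids
    of interior codons are drawn uniformly; the synonymous codon is
    drawn from the genome's group frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    mean_len, sd_len = spec.orf_length_codons
    aa_list = sorted(AA_FAMILIES)
    group_freqs = [_family_frequencies(rng, spec.bias_strength)
                   for _ in spec.group_sizes]
    for freqs in group_freqs:
        for aa, f in freqs.items():
            if not np.all(np.isfinite(f)) or f.sum() <= 0:
                raise ValueError(f"degenerate frequency vector for {aa}")
    cds: dict[str, list[str]] = {}
    groups: dict[str, str] = {}
    for gi, size in enumerate(spec.group_sizes):
        freqs = group_freqs[gi]
        for j in range(size):
            gid = f"grp{gi + 1:02d}_{j + 1:02d}"
            groups[gid] = f"group{gi + 1}"
            orfs = []
            for _ in range(spec.orfs_per_genome):
                n_codons = max(spec.min_codons,
                               int(round(rng.normal(mean_len, sd_len))))
                interior = []
                for _ in range(n_codons - 2):
                    aa = aa_list[rng.integers(len(aa_list))]
                    fam = AA_FAMILIES[aa]
                    codon = fam[rng.choice(len(fam), p=freqs[aa])]
                    interior.append(codon)
                stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
                orfs.append(START_CODON + "".join(interior) + stop)
            cds[gid] = orfs
    return cds, groups


def write_cds_fasta(cds: Mapping[str, Sequence[str]],
                    sink: PathOrStream) -> None:
    """Write generated CDS as FASTA, one record per ORF."""
    fh, close = _open(sink, "w")
    try:
        for gid in cds:
            for k, seq in enumerate(cds[gid], start=1):
                fh.write(f">{gid}|orf{k:04d}\n{seq}\n")
    finally:
        if close:
            fh.close()


def read_cds_fasta(source: PathOrStream) -> dict[str, list[str]]:
    """Read a ``genome|orf`` FASTA back into per-genome CDS lists."""
    fh, close = _open(source)
    try:
        cds: dict[str, list[str]] = {}
        gid = None
        for ln in fh:
            ln = ln.strip()
            if ln.startswith(">"):
                gid = ln[1:].split("|")[0]
                cds.setdefault(gid, []).append("")
            elif gid is not None:
                cds[gid][-1] += ln
        return cds
    finally:
        if close:
            fh.close()


def gen_hit_table(n_queries: int, fraction_conserved: float,
                  preset: FilterPreset = POCP_PRESET, seed: int = 0,
                  n_boundary: int = 0
                  ) -> tuple[list[HitRecord], list[HitRecord], PocpInputs]:
    """Generate two directional hit tables with planted pass labels.

    Each genome has ``n_queries`` proteins; a planted fraction gets a
    clearly passing hit against the other genome, the rest get hits
    failing exactly one criterion each (cycling through the three).
    ``n_boundary`` extra queries per genome get records sitting exactly
    on the identity and coverage thresholds, which pass only under an
    inclusive preset.  The expected conserved/total counts are derived
    from the planted labels, never from re-filtering.
    """
    if not 0.0 <= fraction_conserved <= 1.0:
        raise ValueError("fraction_conserved must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cons = int(round(fraction_conserved * n_queries))
    inclusive = preset.strictness == "inclusive"

    def one_direction(tag: str, sub: str) -> list[HitRecord]:
        hits = []
        order = rng.permutation(n_queries)
        for k, q in enumerate(order):
            qid = f"{tag}_p{q + 1:04d}"
            if k < n_cons:  # clearly passing: generous margins
                hits.append(HitRecord(
                    query_id=qid, subject_id=f"{sub}_p{q + 1:04d}",
                    evalue=float(10 ** rng.uniform(-30, -10)),
                    pct_identity=float(rng.uniform(
                        preset.min_identity + 5, 95)),
                    aln_length=200, query_length=250,
                    query_coverage=float(rng.uniform(
                        preset.min_coverage + 5, 100))))
            else:  # fail exactly one criterion
                mode = k % 3
                hits.append(HitRecord(
                    query_id=qid, subject_id=f"{sub}_p{q + 1:04d}",
                    evalue=1e-3 if mode == 0 else 1e-20,
                    pct_identity=(preset.min_identity - 10) if mode == 1
                    else preset.min_identity + 10,
                    aln_length=200, query_length=250,
                    query_coverage=(preset.min_coverage - 10) if mode == 2
                    else preset.min_coverage + 10))
        for b in range(n_boundary):
            hits.append(HitRecord(
                query_id=f"{tag}_b{b + 1:04d}", subject_id=f"{sub}_bnd",
                evalue=1e-20, pct_identity=preset.min_identity,
                aln_length=200, query_length=250,
                query_coverage=preset.min_coverage))
        return hits

    hits_ab = one_direction("g1", "g2")
    hits_ba = one_direction("g2", "g1")
    c = n_cons + (n_boundary if inclusive else 0)
    t = n_queries + n_boundary
    expected = PocpInputs(c1=c, c2=c, t1=t, t2=t)
    return hits_ab, hits_ba, expected
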