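"""Protein search hit filtering, POCP, and gene-screen counting.

POCP (percentage of conserved proteins) counts, for each genome of a
pair, the query proteins with at least one passing hit against the
other genome's proteome:

    POCP = (C1 + C2) / (T1 + T2) × 100

with C_i conserved-protein counts and T_i total proteome sizes.  The
POCP preset keeps hits with E-value < 1e−5, identity > 40% and query
coverage > 50% (strict inequalities, following the usual wording
"less than / over").  The metal-resistance gene screen uses the same
machinery with an inclusive preset: E < 1e−5, coverage ≥ 70%,
identity ≥ 30%.

Hit tables are BLAST/DIAMOND tabular (outfmt 6) with optional ``qlen``
and ``qcovhsp`` columns; the alignment step itself is external.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from taxodelin.matrix_io import PathOrStream, _open

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One protein search hit (one HSP; HSPs are never merged)."""

    query_id: str
    subject_id: str
    evalue: float
    pct_identity: float
    aln_length: int
    query_length: int | None = None
    query_coverage: float | None = None

    def coverage(self) -> float:
        """Query coverage in percent, derived from qlen when absent."""
        if self.query_coverage is not None:
            return self.query_coverage
        if self.query_length:
            return 100.0 * self.aln_length / self.query_length
        raise ValueError(
            f"hit {self.query_id} vs {self.subject_id}: neither "
            "query_coverage nor query_length available")


@dataclass(frozen=True)
class FilterPreset:
    """Hit-retention thresholds.

    ``strictness='strict'`` keeps identity > min and coverage > min;
    ``'inclusive'`` keeps identity ≥ min and coverage ≥ min.  The
    E-value bound is strict (E < max) in both modes.
    """

    max_evalue: float
    min_identity: float
    min_coverage: float
    strictness: str = "strict"

    def __post_init__(self) -> None:
        if self.strictness not in ("strict", "inclusive"):
            raise ValueError("strictness must be 'strict' or 'inclusive'")
        if not (self.max_evalue >= 0 and 0 <= self.min_identity <= 100
                and 0 <= self.min_coverage <= 100):
            raise ValueError("thresholds out of range")

    def passes(self, hit: HitRecord) -> bool:
        if not hit.evalue < self.max_evalue:
            return False
        if self.strictness == "strict":
            return (hit.pct_identity > self.min_identity
                    and hit.coverage() > self.min_coverage)
        return (hit.pct_identity >= self.min_identity
                and hit.coverage() >= self.min_coverage)


#: conserved-protein criteria for POCP
POCP_PRESET = FilterPreset(max_evalue=1e-5, min_identity=40.0,
                           min_coverage=50.0, strictness="strict")
#: metal-resistance gene screen criteria
METAL_PRESET = FilterPreset(max_evalue=1e-5, min_identity=30.0,
                            min_coverage=70.0, strictness="inclusive")


@dataclass(frozen=True)
class PocpInputs:
    """Conserved (c) and total (t) protein counts for a genome pair."""

    c1: int
    c2: int
    t1: int
    t2: int

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("total protein counts must be positive")
        if not (0 <= self.c1 <= self.t1 and 0 <= self.c2 <= self.t2):
            raise ValueError(
                "conserved counts must lie in [0, total] for each genome")


def read_hit_table(source: PathOrStream,
                   columns: Sequence[str] | None = None) -> list[HitRecord]:
    """Read a BLAST/DIAMOND tabular file into HitRecords.

    ``columns`` declares the column order (default: standard 12-column
    outfmt 6); ``qlen`` and ``qcovhsp`` are recognized extras.
    """
    fh, close = _open(source)
    try:
        df = pd.read_csv(fh, sep="\t", header=None, comment="#")
    finally:
        if close:
            fh.close()
    if columns is not None:
        cols = list(columns)
    else:
        # infer the dialect from the field count: 12 standard columns,
        # optionally followed by qlen and qcovhsp
        cols = list(OUTFMT6_COLUMNS) + ["qlen", "qcovhsp"][:max(
            0, df.shape[1] - len(OUTFMT6_COLUMNS))]
    if df.shape[1] != len(cols):
        raise ValueError(
            f"hit table has {df.shape[1]} columns, expected {len(cols)}")
    df.columns = cols
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(HitRecord(
            query_id=str(d["qseqid"]), subject_id=str(d["sseqid"]),
            evalue=float(d["evalue"]), pct_identity=float(d["pident"]),
            aln_length=int(d["length"]),
            query_length=int(d["qlen"]) if "qlen" in d else None,
            query_coverage=float(d["qcovhsp"]) if "qcovhsp" in d else None))
    return records


def write_hit_table(hits: Iterable[HitRecord], sink: PathOrStream) -> None:
    """Write hits as 12-column outfmt 6 plus qlen and qcovhsp."""
    fh, close = _open(sink, "w")
    try:
        for h in hits:
            qlen = h.query_length if h.query_length is not None else 0
            fields = [h.query_id, h.subject_id, f"{h.pct_identity:.1f}",
                      str(h.aln_length), "0", "0", "1", str(h.aln_length),
                      "1", str(h.aln_length), f"{h.evalue:.2e}", "100",
                      str(qlen), f"{h.coverage():.1f}"]
            fh.write("\t".join(fields) + "\n")
    finally:
        if close:
            fh.close()


def filter_hits(hits: Iterable[HitRecord],
                preset: FilterPreset) -> list[HitRecord]:
    """Return the hits passing all three preset criteria.

    Each record is judged alone (multiple HSPs of a pair are not
    merged).  A record lacking both coverage and query length raises.
    """
    return [h for h in hits if preset.passes(h)]


def conserved_counts(hits_ab: Iterable[HitRecord],
                     hits_ba: Iterable[HitRecord],
                     preset: FilterPreset = POCP_PRESET) -> tuple[int, int]:
    """Distinct query proteins with ≥1 passing hit, per direction.

    Returns ``(c1, c2)``: c1 counts genome 1 queries conserved in
    genome 2 (from the A→B search) and c2 the reverse.
    """
    c1 = len({h.query_id for h in filter_hits(hits_ab, preset)})
    c2 = len({h.query_id for h in filter_hits(hits_ba, preset)})
    return c1, c2


def compute_pocp(inputs: PocpInputs) -> float:
    """POCP = (c1 + c2) / (t1 + t2) × 100, symmetric in the two genomes."""
    return 100.0 * (inputs.c1 + inputs.c2) / (inputs.t1 + inputs.t2)


def pocp_from_hit_tables(hits_ab: Iterable[HitRecord],
                         hits_ba: Iterable[HitRecord],
                         t1: int, t2: int,
                         preset: FilterPreset = POCP_PRESET) -> float:
    """End-to-end POCP from the two directional hit tables."""
    c1, c2 = conserved_counts(hits_ab, hits_ba, preset)
    return compute_pocp(PocpInputs(c1=c1, c2=c2, t1=t1, t2=t2))


def count_gene_hits(hits: Iterable[HitRecord], preset: FilterPreset,
                    family_map: Mapping[str, str],
                    total_proteins: int | None = None,
                    ) -> dict[str, float]:
    """Per-family counts of distinct passing query proteins.

    Subjects absent from ``family_map`` are bucketed as ``unassigned``
    with a warning.  When ``total_proteins`` is given, counts are
    normalized to per-total-protein relative abundance.
    """
    queries_by_family: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for h in filter_hits(hits, preset):
        fam = family_map.get(h.subject_id)
        if fam is None:
            unmapped.add(h.subject_id)
            fam = "unassigned"
        queries_by_family.setdefault(fam, set()).add(h.query_id)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} subject id(s) missing from the family map, "
            f"bucketed as 'unassigned': {sorted(unmapped)[:5]}",
            stacklevel=2)
    counts = {fam: float(len(qs)) for fam, qs in queries_by_family.items()}
    if total_proteins:
        counts = {fam: c / total_proteins for fam, c in counts.items()}
    return counts


def proteome_size(fasta: PathOrStream) -> int:
    """Number of sequences in a protein FASTA (the T_i of POCP)."""
    fh, close = _open(fasta)
    try:
        return sum(1 for ln in fh if ln.startswith(">"))
    finally:
        if close:
            fh.close()
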