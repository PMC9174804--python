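# Methods

## Identity matrices

An `IdentityMatrix` stores one percent identity per genome pair, in
[0, 100], rounded to two decimals — the same granularity as the 0.01
threshold grid, so no information relevant to the sweep is lost.  The
diagonal is self-identity and is always coerced to 100; it never
enters clustering decisions.  One-way AAI calculators can return
slightly different values for A→B and B→A; since the clustering treats
identity as a single pairwise quantity, the two cells are averaged on
ingestion and a discrepancy above 0.5 percentage points triggers a
warning.  Symmetrization is idempotent.  Missing cells are tolerated in
reports but rejected by the optimizer, which needs a complete matrix.
Both square and lower-triangle TSV/CSV layouts are accepted, because
published supplementary tables come in either.

## The threshold sweep

Thresholds are represented internally on an integer centi-percent grid
(6000…8000 for the default 60.00–80.00 range, 2001 points), which makes
0.01-stepping exact and immune to floating-point drift.  At each grid
point the genome-by-genome boolean neighbor matrix is built and its
unique rows are the deduplicated clusters; this vectorized form is
equivalent to the per-genome set construction (property-tested against
a loop-based brute force for small n at every grid threshold).

**Edge rule.**  A genome joins a neighborhood when identity ≥ t
(inclusive) by default.  On a 0.01 grid the strict alternative only
shifts plateau boundaries by one grid step; both are available
(`edge_rule="ge"|"gt"`).

**Penalties.**  The scoring constraint is an ordering: the
multi-membership deduction must exceed the total number of genomes, and
the singleton deduction is small.  The defaults are the smallest
integers satisfying it — p_multi = n + 1 per extra membership,
p_single = 1 per singleton — so one monophyly violation always
outweighs any attainable number of singleton deductions.  The
multi-membership penalty is charged per extra membership of *every*
genome, not only the hub: in the A/B/C overlap case A contributes 2
extra memberships and B and C one each, giving score
−(n + 1) × 4 with no singletons.  Both penalties are configurable,
including for the open question of whether genuinely monotypic genera
should be charged at all (set `p_single=0` to exempt them).

**Plateaus.**  Maximal contiguous runs of equal score are reported as
center ± half-width.  Ranking is by score, then by plateau width
(wider ranges are more robust cut-offs), then by lower center.  All
plateaus are reported with their scores; no top-k selection is imposed,
since any choice beyond "maximum score" would be arbitrary.  A
plateau's cluster count is taken at its center grid point (equal-score
runs can in principle mix cluster counts, though none do in practice on
gap-structured matrices).

## Genus and species rules

`delineate_genera` applies a cut-off and *checks* monophyly: if any
genome falls in more than one cluster the cut is rejected with the
offending genomes and their cluster counts, rather than silently
merging or splitting.  The species rule is pairwise: same species
requires ANI ≥ 95 *and* dDDH ≥ 70 (difference is "under the cut-off",
so the boundary itself is conspecific).  The ANI cut is configurable
across the commonly used 95–96 band, and pairs whose ANI falls inside
[95, 96) are flagged borderline.  Species groups are the connected
components of the same-species graph; because a pairwise rule need not
be transitive, non-transitive triples are detected and reported as a
warning rather than hidden.  Raising either cut only refines the
grouping (property-tested).

## POCP and the gene screen

POCP = (C₁ + C₂)/(T₁ + T₂) × 100, with C_i the number of *distinct*
query proteins of genome i having at least one passing hit against the
other proteome (distinct-query counting is standard POCP practice) and
T_i the proteome sizes (sequence counts of the input FASTAs).  The
conserved-protein filter is strict per its usual phrasing — E < 10⁻⁵,
identity > 40%, coverage > 50% — while the metal-resistance screen is
inclusive: E < 10⁻⁵, coverage ≥ 70%, identity ≥ 30% ("similarity" is
mapped to the identity column of tabular search output, which carries
no separate similarity figure).  Query coverage, when the table lacks
`qcovhsp`, is derived as 100 · aln_length / qlen; multiple HSPs of a
pair are judged independently because no merging rule is defined for
this filter.  The alignment search itself (BLASTP/DIAMOND) is external;
only its tabular output is consumed.

## Codon-usage validation

**ORFs.**  ATG-initiated, stop-terminated spans under translation
table 11, scanned in all three frames of one or both strands.  Only the
longest ORF per (frame, stop) is kept — the 5′-most ATG after the
previous in-frame stop — so nested starts never double-count codons.
The codon count includes the start and the stop codon.  The default
minimum of 50 codons is a common short-ORF floor; it is configurable
since the tool this emulates does not document its setting.  Codons
containing N are skipped with a diagnostic.

**RSCU.**  For codon c in a synonymous family of size k,
RSCU(c) = count(c) · k / family total.  Met, Trp and the three stops
are excluded, leaving a fixed 59-codon vector.  Families with zero
usage are kept as zeros and flagged, preserving vector length for the
PCA.  Family sums equal k and family means equal 1 for every nonzero
family (property-tested).

**PCA.**  Mean-centered, unscaled (`prcomp`-default behaviour), full
SVD, with a deterministic sign convention: the largest-magnitude
loading of each component is made positive.  Inter-genome distances are
Euclidean on the first three components.

**ANOSIM.**  R = (mean between-group rank − mean within-group rank) /
(M/2) over the tie-averaged ranks of all M = n(n−1)/2 pairwise
dissimilarities; R ∈ [−1, 1], and is invariant under monotone
transforms of the dissimilarities.  The permutation p-value uses the
+1 correction, so p ≥ 1/(permutations + 1); 9,999 permutations with a
mandatory seed is the default (a reported p of 10⁻⁴ is exactly this
floor).  An exact mode enumerates every distinct label arrangement for
small n and is cross-checked in tests against a brute-force
enumeration and against scikit-bio's implementation.  Bray–Curtis is
the default dissimilarity with Euclidean available; on RSCU vectors
the two give very similar rank structure, and the choice is exposed
because the convention varies between analysis packages.

## Synthetic data

The generators are pure functions of (spec, seed) and always emit the
planted truth alongside the data; recovery tests compare pipeline
output to that truth, never to re-derived values.

*Identity matrices.*  Within-group identities ~ N(78, 1), between-group
~ N(58, 1), clamped to [0, 100] — a wide gap around genus-level
cut-offs so the planted partition is recoverable at any threshold
inside the gap; a guarantee-gap flag errors out if sampling ever closes
the gap.  Normal-with-clamping keeps the gap directly controllable;
heavy tails would only blur what the tests need sharp.  Bridge genomes
receive within-level identity to the members of two host groups,
reproducing the overlap pattern the optimizer penalizes.  The
acceptance script uses 27 groups over 88 genomes (sizes from 13 down to
10 monotypic singletons) as a study-shaped instance; sizes within that
shape are a package choice.

*Coding sequences.*  Each group draws per-family codon frequencies from
a Dirichlet with concentration 1/bias_strength (per family, so family
sums are valid by construction); bias_strength 0 pins all groups to
uniform usage — the ANOSIM null.  Genome CDS are sampled codon by
codon (uniform amino acids, group-specific synonymous choice), ATG
prepended, a stop appended, and contain no internal stop by
construction.  Defaults — 3 groups of 5 genomes, 40 ORFs per genome of
200 ± 50 codons, bias_strength 1 — are desk-scale but large enough
that RSCU estimates are stable per genome.

*Hit tables.*  Conserved queries receive clearly passing hits,
non-conserved queries hits failing exactly one criterion (cycling
through the three), and optional boundary records sit exactly on the
identity and coverage thresholds, so strict and inclusive presets give
opposite outcomes on them.  Expected POCP inputs are derived from the
planted labels at generation time.

What the generators deliberately do **not** model: phylogenetic
correlation between genomes, identity distributions with heavy tails or
within/between overlap (real families have both — the optimizer then
reports negative-score plateaus rather than a clean 0), genome-wide
G+C/strand-skew gradients in codon usage, and paralogy structure in hit
tables.  Passing the recovery tests therefore shows the machinery is
correct under its stated assumptions, not that any particular real
family satisfies them.

## Problem sizes and numerics

The default sweep evaluates 2001 thresholds; on ~100 genomes it runs in
a couple of seconds (boolean row deduplication per grid point).  Test
and acceptance workloads use tens of genomes and hundreds of
permutations to stay fast while keeping every statistical check
meaningful; the acceptance script's ANOSIM uses the full 9,999
permutations.  All stochastic steps take explicit seeds
(`numpy.random.default_rng`); CLI runs write a JSON provenance record
and are byte-identical under a fixed config and seed.

## Known limitations

* The optimizer assumes a complete matrix; partially compared genome
  sets must be completed or subset first.
* Plateau selection beyond "top score, widest, lowest center" is left
  to the user; candidate plateaus other than the top one are reported,
  not interpreted.
* ANOSIM permutes labels freely and so assumes exchangeability of
  genomes under the null; phylogenetic non-independence is not
  corrected for.
* The POCP module consumes search output; results inherit whatever
  search sensitivity produced the hit tables.
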