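import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from taxodelin import (CodonCounts, Embedding, Orf, anosim,
                       count_codons, count_codons_cds, distance3d,
                       find_orfs, group_distance_stats, pca_embed,
                       profiles_from_cds, rscu)
from taxodelin.codon_usage import (AA_FAMILIES, ALL_CODONS, RSCU_CODONS,
                                   RscuProfile, orf_codons)

REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(REVCOMP)[::-1]


def make_counts(mapping, genome_id="g"):
    counts = {c: 0 for c in ALL_CODONS}
    counts.update(mapping)
    return CodonCounts(genome_id=genome_id, counts=counts)


class TestFindOrfs:
    def test_minimal_orf_three_codons(self):
        (o,) = find_orfs("ATGAAATAA", min_codons=2, strands="forward")
        assert (o.start, o.end, o.strand, o.n_codons) == (0, 9, "+", 3)

    def test_no_atg_no_orfs(self):
        assert find_orfs("CCCCCC", min_codons=1, strands="both") == []

    def test_min_codons_filter(self):
        assert find_orfs("ATGAAATAA", min_codons=4, strands="forward") == []

    def test_five_prime_most_atg_reported(self):
        # two in-frame ATGs before one stop: the maximal ORF is reported
        seq = "ATGCCCATGAAATAA"
        (o,) = find_orfs(seq, min_codons=2, strands="forward")
        assert o.start == 0 and o.n_codons == 5

    def test_internal_stop_splits_orfs(self):
        seq = "ATGAAATAAATGCCCTGA"
        orfs = find_orfs(seq, min_codons=2, strands="forward")
        assert [(o.start, o.end) for o in orfs] == [(0, 9), (9, 18)]

    def test_reverse_strand_codons_match_forward_call(self):
        fwd = "ATGGCTAAACCCGGGTAA"
        genome = "TT" + rc(fwd) + "CAC"
        orfs = find_orfs(genome, min_codons=2, strands="both")
        minus = [o for o in orfs if o.strand == "-"]
        assert len(minus) == 1
        assert orf_codons(minus[0], genome) == \
            orf_codons(Orf("f", 0, 18, "+", 0, 6), fwd)

    def test_forward_only_skips_reverse(self):
        genome = rc("ATGGCTAAACCCGGGTAA")
        assert find_orfs(genome, 2, strands="forward") == []

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            find_orfs("ATGXXXTAA", 1)


class TestCountCodons:
    def test_single_orf_tally(self):
        seq = "ATGAAATAA"
        (o,) = find_orfs(seq, 2, "forward")
        cc = count_codons([o], seq)
        assert {c: n for c, n in cc.counts.items() if n} == \
            {"ATG": 1, "AAA": 1, "TAA": 1}

    def test_two_identical_orfs_double_counts(self):
        seq = "ATGAAATAA"
        o = find_orfs(seq, 2, "forward")[0]
        cc = count_codons([o, o], seq)
        assert cc.counts["AAA"] == 2 and cc.total == 6

    def test_hand_tally_over_toy_orfs(self):
        cds = ["ATGAAATAA", "ATGAAAAAATAG", "ATGCCCTGA",
               "ATGGGGCCCTAA", "ATGTTTTGA"]
        cc = count_codons_cds("g", cds)
        # enumerate by hand over all 5 CDS
        expect = {"ATG": 5, "AAA": 3, "CCC": 2, "GGG": 1, "TTT": 1,
                  "TAA": 2, "TAG": 1, "TGA": 2}
        assert {c: n for c, n in cc.counts.items() if n} == expect
        assert cc.n_orfs == 5

    def test_ambiguous_codons_skipped_with_diagnostic(self):
        with pytest.warns(UserWarning, match="skipped"):
            cc = count_codons_cds("g", ["ATGANATAA"])
        assert cc.counts["ATG"] == 1 and cc.n_skipped_ambiguous == 1


class TestRscu:
    def test_uniform_two_codon_family(self):
        # Lys family AAA/AAG used 10/10 -> both exactly 1.0
        prof = rscu(make_counts({"AAA": 10, "AAG": 10}))
        assert prof.rscu["AAA"] == prof.rscu["AAG"] == 1.0

    def test_maximal_bias_six_codon_family(self):
        leu = AA_FAMILIES["L"]
        assert len(leu) == 6
        prof = rscu(make_counts({"CTG": 12}))
        assert prof.rscu["CTG"] == 6.0
        assert all(prof.rscu[c] == 0.0 for c in leu if c != "CTG")

    def test_hand_computed_vector(self):
        # Phe: TTT=3, TTC=1 -> 3*2/4=1.5 and 1*2/4=0.5
        prof = rscu(make_counts({"TTT": 3, "TTC": 1, "AAA": 2}))
        assert prof.rscu["TTT"] == 1.5
        assert prof.rscu["TTC"] == 0.5
        assert prof.rscu["AAA"] == 2.0  # AAG unused

    def test_met_trp_stops_excluded(self):
        prof = rscu(make_counts({"ATG": 5, "TGG": 5, "TAA": 5, "AAA": 1}))
        assert len(prof.rscu) == 59
        for c in ("ATG", "TGG", "TAA", "TAG", "TGA"):
            assert c not in prof.rscu

    def test_zero_family_flagged_not_dropped(self):
        prof = rscu(make_counts({"AAA": 4}))
        assert "F" in prof.zero_families
        assert prof.rscu["TTT"] == 0.0
        assert len(prof.as_vector()) == 59

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            rscu(make_counts({}))

    @given(st.lists(st.integers(0, 50), min_size=59, max_size=59))
    def test_family_sums_and_means_conserved(self, raw):
        """Σ RSCU over a nonzero family = family size; mean = 1."""
        counts = make_counts(dict(zip(RSCU_CODONS, raw)))
        if counts.total == 0:
            return
        prof = rscu(counts)
        for aa, fam in AA_FAMILIES.items():
            if aa in ("M", "W"):
                continue
            tot = sum(counts.counts[c] for c in fam)
            s = sum(prof.rscu[c] for c in fam)
            if tot:
                assert s == pytest.approx(len(fam), abs=1e-9)
                assert s / len(fam) == pytest.approx(1.0)
            else:
                assert s == 0.0


def random_profiles(n, seed):
    rng = np.random.default_rng(seed)
    profs = []
    for i in range(n):
        raw = rng.integers(1, 100, size=len(RSCU_CODONS))
        profs.append(rscu(make_counts(dict(zip(RSCU_CODONS, raw)),
                                      genome_id=f"g{i}")))
    return profs


class TestPcaEmbed:
    def test_two_profiles_one_informative_component(self):
        emb = pca_embed(random_profiles(2, 0), k=1)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_exact_rank_three_data_fully_explained(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(3, 59))
        weights = rng.normal(size=(10, 3))
        X = weights @ basis + rng.normal(size=59)  # 3-dim affine subspace
        profs = [RscuProfile(f"g{i}", dict(zip(RSCU_CODONS, row)))
                 for i, row in enumerate(X)]
        emb = pca_embed(profs, k=3)
        assert emb.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_explained_ratios_non_increasing_in_unit_interval(self):
        emb = pca_embed(random_profiles(12, 3), k=5)
        r = emb.explained_variance_ratio
        assert np.all(r >= 0) and np.all(r <= 1) and r.sum() <= 1 + 1e-9
        assert np.all(np.diff(r) <= 1e-12)

    def test_full_rank_projection_preserves_pairwise_distances(self):
        profs = random_profiles(8, 5)
        _, X = np.array([p.genome_id for p in profs]), \
            np.vstack([p.as_vector() for p in profs])
        emb = pca_embed(profs, k=7)  # k = n - 1: lossless for centered data
        assert np.allclose(pdist(emb.coordinates), pdist(X), atol=1e-8)

    def test_sign_convention_deterministic(self):
        a = pca_embed(random_profiles(6, 8), k=3)
        b = pca_embed(random_profiles(6, 8), k=3)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_constant_profiles_rejected(self):
        profs = [RscuProfile(f"g{i}", dict.fromkeys(RSCU_CODONS, 1.0))
                 for i in range(4)]
        with pytest.raises(ValueError, match="constant"):
            pca_embed(profs, k=2)


class TestDistance3d:
    @staticmethod
    def embed(points):
        return Embedding([f"g{i}" for i in range(len(points))],
                         np.asarray(points, float),
                         np.array([0.5, 0.3, 0.2]))

    def test_identical_points_distance_zero(self):
        e = self.embed([[1, 2, 3], [1, 2, 3]])
        assert distance3d(e, "g0", "g1") == 0.0

    def test_closed_form_1_2_2(self):
        e = self.embed([[0, 0, 0], [1, 2, 2]])
        assert distance3d(e, "g0", "g1") == 3.0

    def test_missing_id_raises(self):
        e = self.embed([[0, 0, 0], [1, 1, 1]])
        with pytest.raises(KeyError):
            distance3d(e, "g0", "nope")

    def test_group_stats_match_pair_enumeration(self):
        pts = np.random.default_rng(2).normal(size=(5, 3))
        e = self.embed(pts)
        ids = e.genome_ids
        d = [float(np.linalg.norm(pts[i] - pts[j]))
             for i, j in itertools.combinations(range(5), 2)]
        mean, sd = group_distance_stats(e, ids)
        assert mean == pytest.approx(np.mean(d))
        assert sd == pytest.approx(np.std(d))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_distance_is_a_metric(self, seed):
        pts = np.random.default_rng(seed).normal(size=(3, 3))
        e = self.embed(pts)
        a, b, c = e.genome_ids
        dab, dbc, dac = (distance3d(e, a, b), distance3d(e, b, c),
                         distance3d(e, a, c))
        assert dab >= 0 and dab == distance3d(e, b, a)
        assert dac <= dab + dbc + 1e-12


def oracle_anosim_r(dist, labels):
    """Independent R: explicit tie-averaged ranking with plain loops."""
    n = len(labels)
    pairs = [(dist[i][j], labels[i] == labels[j])
             for i in range(n) for j in range(i + 1, n)]
    order = sorted(range(len(pairs)), key=lambda k: pairs[k][0])
    ranks = [0.0] * len(pairs)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and \
                pairs[order[j + 1]][0] == pairs[order[k]][0]:
            j += 1
        avg = (k + j) / 2 + 1
        for idx in order[k:j + 1]:
            ranks[idx] = avg
        k = j + 1
    within = [r for r, (_, same) in zip(ranks, pairs) if same]
    between = [r for r, (_, same) in zip(ranks, pairs) if not same]
    m = len(pairs)
    return (sum(between) / len(between) - sum(within) / len(within)) / (m / 2)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        X = np.vstack([np.zeros((3, 4)), np.ones((3, 4)) * 5])
        X += np.random.default_rng(0).normal(0, 0.01, X.shape)
        res = anosim(X, ["a"] * 3 + ["b"] * 3, n_permutations=99,
                     metric="euclidean", seed=1)
        assert res.r_statistic == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self):
        """6 samples, 2 groups of 3: all distinct relabelings enumerated."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 5))
        X[:3] += 2.0
        labels = ["a", "a", "a", "b", "b", "b"]
        dist = squareform(pdist(X, metric="euclidean"))
        r_obs = oracle_anosim_r(dist.tolist(), labels)
        perms = {p for p in itertools.permutations(labels)}
        assert len(perms) == 20
        r_all = [oracle_anosim_r(dist.tolist(), list(p)) for p in perms]
        p_exact = sum(r >= r_obs - 1e-12 for r in r_all) / len(r_all)
        res = anosim(X, labels, metric="euclidean", exact=True)
        assert res.r_statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(p_exact)
        assert res.n_permutations == 20

    def test_r_matches_loop_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(9, 6))
        labels = ["a", "b", "c"] * 3
        res = anosim(X, labels, n_permutations=99, metric="euclidean",
                     seed=0)
        dist = squareform(pdist(X, metric="euclidean"))
        assert res.r_statistic == pytest.approx(
            oracle_anosim_r(dist.tolist(), labels))

    def test_agrees_with_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 8))
        X[:5] += 1.0
        labels = ["a"] * 5 + ["b"] * 5
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i)
                                                       for i in range(10)])
        expected = sk_anosim(dm, labels, permutations=0)["test statistic"]
        res = anosim(X, labels, n_permutations=999, metric="euclidean",
                     seed=3)
        assert res.r_statistic == pytest.approx(float(expected))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        labels = ["a"] * 4 + ["b"] * 4
        d = squareform(pdist(X))
        r1 = anosim(d, labels, metric="precomputed", n_permutations=99,
                    seed=0).r_statistic
        r2 = anosim(np.exp(d) - 1, labels, metric="precomputed",
                    n_permutations=99, seed=0).r_statistic
        assert r1 == pytest.approx(r2)

    def test_seed_reproducible(self):
        profs = random_profiles(8, 13)
        groups = {p.genome_id: ("a" if i < 4 else "b")
                  for i, p in enumerate(profs)}
        a = anosim(profs, groups, n_permutations=199, seed=42)
        b = anosim(profs, groups, n_permutations=199, seed=42)
        assert (a.r_statistic, a.p_value) == (b.r_statistic, b.p_value)

    def test_p_value_floor(self):
        X = np.vstack([np.zeros((4, 3)), np.ones((4, 3))])
        X += np.random.default_rng(1).normal(0, 0.01, X.shape)
        res = anosim(X, ["a"] * 4 + ["b"] * 4, n_permutations=999,
                     metric="euclidean", seed=0)
        assert res.p_value >= 1 / (res.n_permutations + 1)

    def test_degenerate_groupings_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError, match="2 groups"):
            anosim(X, ["a"] * 4, n_permutations=99, seed=0)
        with pytest.raises(ValueError, match="singleton"):
            anosim(X, ["a", "b", "c", "d"], n_permutations=99, seed=0)
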