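"""Selection criteria: GEBV, wGEBV, OHV and EMBV against independent oracles."""

import itertools

import numpy as np
import pytest

import embvsel as e
from embvsel.genome import ConfigError, DataError


def toy_map(positions, length=100.0, chrom=None):
    pos = np.asarray(positions, dtype=float)
    cidx = np.zeros(len(pos), dtype=int) if chrom is None else np.asarray(chrom)
    n_chrom = int(cidx.max()) + 1 if len(pos) else 1
    return e.GeneticMap(np.full(n_chrom, length), pos, cidx,
                        np.array([f"m{i}" for i in range(len(pos))]))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_dh_distribution(candidate, alpha, gmap):
    """Exact DH-GEBV distribution of a candidate by gamete-class enumeration.

    Enumerates every strand pattern over the heterozygous loci; the pattern
    probability is the product of a fair start per chromosome and, between
    consecutive heterozygous loci, the Haldane recombination fraction (switch)
    or its complement (no switch). Feasible for <= ~12 heterozygous loci.
    """
    h1 = candidate.hap1.astype(int)
    h2 = candidate.hap2.astype(int)
    het = np.flatnonzero(h1 != h2)
    base = 2.0 * float(np.asarray(alpha) @ h2)
    beta = 2.0 * np.asarray(alpha)[het] * (h1[het] - h2[het])
    pos = gmap.positions_cM[het]
    chrom = gmap.chrom_index[het]
    H = len(het)
    values, probs = [], []
    for bits in itertools.product((0, 1), repeat=H):
        pr = 1.0
        for i in range(H):
            if i == 0 or chrom[i] != chrom[i - 1]:
                pr *= 0.5
            else:
                r = e.recombination_fraction(pos[i] - pos[i - 1])
                pr *= r if bits[i] != bits[i - 1] else (1.0 - r)
        values.append(base + sum(b * w for b, w in zip(bits, beta)))
        probs.append(pr)
    return np.array(values), np.array(probs)


def exact_expected_max(values, probs, ng):
    """E[max of ng i.i.d. draws] from a finite distribution, exactly."""
    order = np.argsort(values)
    v = values[order]
    F = np.cumsum(probs[order])
    F = F / F[-1]
    F_prev = np.r_[0.0, F[:-1]]
    return float(np.sum(v * (F ** ng - F_prev ** ng)))


def brute_force_ohv(candidate, alpha, partition):
    """Best DH over all segment-wise haplotype choices, exhaustively."""
    best = -np.inf
    haps = [candidate.hap1.astype(float), candidate.hap2.astype(float)]
    segs = partition.segments
    for choice in itertools.product((0, 1), repeat=len(segs)):
        gam = np.concatenate([haps[c][s:t] for c, (s, t) in zip(choice, segs)])
        best = max(best, 2.0 * float(gam @ np.asarray(alpha)))
    return best


# ---------------------------------------------------------------------------
# GEBV / wGEBV
# ---------------------------------------------------------------------------

class TestGebv:
    def test_single_locus_dosages(self):
        scores = e.gebv(np.array([[0], [1], [2]]), np.array([1.0]))
        np.testing.assert_allclose(scores, [0, 1, 2])

    def test_five_locus_hand_sum(self):
        x = np.array([[2, 1, 0, 2, 1]])
        alpha = np.array([0.3, 1.1, 0.7, 0.2, 0.9])
        assert e.gebv(x, alpha)[0] == pytest.approx(
            2 * 0.3 + 1 * 1.1 + 0 * 0.7 + 2 * 0.2 + 1 * 0.9)

    def test_zero_effects(self):
        assert np.all(e.gebv(np.array([[1, 2]]), np.zeros(2)) == 0)


class TestWgebv:
    def test_weight_at_half_is_pi_over_two(self):
        assert e.wgebv_weights(np.array([0.5]))[0] == pytest.approx(np.pi / 2)

    def test_weights_increase_as_favorable_allele_gets_rarer(self):
        ps = np.array([0.4, 0.2, 0.1, 0.02, 0.001])
        w = e.wgebv_weights(ps)
        assert np.all(np.diff(w) > 0)

    def test_fixed_loci_get_zero_weight(self):
        np.testing.assert_allclose(e.wgebv_weights(np.array([0.0, 1.0])), 0.0)

    def test_constant_weight_factors_out(self, rng):
        X = rng.integers(0, 3, size=(6, 8))
        alpha = rng.gamma(1.66, 0.4, 8)
        p = np.full(8, 0.5)
        np.testing.assert_allclose(e.wgebv(X, alpha, p),
                                   (np.pi / 2) * e.gebv(X, alpha))

    def test_frequency_change_can_reorder_candidates(self):
        # two loci, equal alpha; candidate A carries the common allele twice,
        # candidate B the rare one twice: wGEBV prefers B once p1 >> p2
        X = np.array([[2, 0], [0, 2]])
        alpha = np.array([1.0, 1.0])
        equal = e.wgebv(X, alpha, np.array([0.5, 0.5]))
        assert equal[0] == pytest.approx(equal[1])
        skew = e.wgebv(X, alpha, np.array([0.9, 0.1]))
        assert skew[1] > skew[0]

    def test_zero_dosage_scores_zero(self):
        assert e.wgebv(np.zeros((1, 3)), np.ones(3), np.full(3, 0.3))[0] == 0.0


# ---------------------------------------------------------------------------
# OHV
# ---------------------------------------------------------------------------

class TestPartition:
    def test_ns_one_is_whole_chromosomes(self, small_map):
        part = e.partition_haplotypes(small_map, 1)
        assert part.n_segments == small_map.n_chrom
        assert part.segments == [(s.start, s.stop) for s in small_map.chrom_slices()]

    def test_half_open_breakpoint_convention(self):
        gmap = toy_map([10.0, 49.9, 50.0, 90.0])
        part = e.partition_haplotypes(gmap, 2)
        assert part.segments == [(0, 2), (2, 4)]

    def test_invalid_ns_rejected(self, small_map):
        with pytest.raises(ConfigError):
            e.partition_haplotypes(small_map, 0)

    def test_short_segments_warn(self, small_map):
        with pytest.warns(UserWarning):
            e.partition_haplotypes(small_map, 32)  # 100/32 cM < 6.25 cM

    @pytest.mark.parametrize("ns", [1, 2, 3, 5, 8])
    def test_segments_partition_all_loci(self, standard_map, ns):
        part = e.partition_haplotypes(standard_map, ns)
        covered = np.concatenate([np.arange(s, t) for s, t in part.segments])
        np.testing.assert_array_equal(covered, np.arange(standard_map.n_loci))


class TestOhv:
    def test_homozygote_ohv_equals_gebv(self, small_map, rng):
        hap = rng.integers(0, 2, small_map.n_loci).astype(np.uint8)
        haps = np.stack([hap, hap])[None]
        alpha = rng.gamma(1.66, 0.4, small_map.n_loci)
        part = e.partition_haplotypes(small_map, 2)
        assert e.ohv(haps, alpha, part)[0] == pytest.approx(
            e.gebv((2 * hap)[None, :], alpha)[0])

    def test_single_segment_takes_better_haplotype_doubled(self):
        gmap = toy_map([20.0, 80.0])
        haps = np.array([[[1, 0], [1, 1]]], dtype=np.uint8)  # values 1.0, 3.0
        part = e.partition_haplotypes(gmap, 1)
        assert e.ohv(haps, np.array([1.0, 2.0]), part)[0] == pytest.approx(6.0)

    def test_matches_exhaustive_segment_choice_oracle(self, rng):
        gmap = e.GeneticMap.equidistant(2, 200.0, 12)
        part = e.partition_haplotypes(gmap, 4)  # 8 segments -> 256 choices
        alpha = rng.gamma(1.66, 0.4, 12)
        for _ in range(10):
            cand = e.PhasedGenotype(rng.integers(0, 2, 12).astype(np.uint8),
                                    rng.integers(0, 2, 12).astype(np.uint8))
            expected = brute_force_ohv(cand, alpha, part)
            assert e.ohv(cand.haps[None], alpha, part)[0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# EMBV
# ---------------------------------------------------------------------------

class TestExpectedMaxStdNormal:
    def test_known_values(self):
        assert e.expected_max_std_normal(1) == 0.0
        assert e.expected_max_std_normal(2) == pytest.approx(
            1 / np.sqrt(np.pi), abs=1e-6)
        # high-resolution quadrature oracle value for ng = 10
        assert e.expected_max_std_normal(10) == pytest.approx(1.53875, abs=1e-5)

    def test_monotone_in_ng(self):
        vals = [e.expected_max_std_normal(n) for n in (1, 2, 5, 10, 50, 200)]
        assert np.all(np.diff(vals) > 0)


class TestDhSdAnalytic:
    def test_homozygote_has_zero_sd(self, small_map):
        hap = np.ones(small_map.n_loci, np.uint8)
        alpha = np.ones(small_map.n_loci)
        assert e.dh_sd_analytic(e.PhasedGenotype(hap, hap.copy()), alpha,
                                small_map) == 0.0

    def test_two_unlinked_het_loci(self):
        gmap = toy_map([25.0, 25.0], chrom=[0, 1], length=50.0)
        cand = e.PhasedGenotype(np.array([1, 1], np.uint8),
                                np.array([0, 0], np.uint8))
        assert e.dh_sd_analytic(cand, np.array([1.0, 1.0]), gmap) == \
            pytest.approx(np.sqrt(2.0))

    def test_matches_monte_carlo_dh_sd(self, rng):
        gmap = toy_map([5.0, 12.0, 30.0, 31.0, 70.0, 99.0])
        cand = e.PhasedGenotype(np.array([1, 0, 1, 1, 0, 1], np.uint8),
                                np.array([0, 1, 0, 1, 1, 0], np.uint8))
        alpha = np.array([0.8, 1.2, 0.3, 0.9, 1.5, 0.4])
        n = 100_000
        gam = e.sample_gametes(cand, gmap, n, rng)
        dh_scores = 2.0 * gam @ alpha
        sd_mc = dh_scores.std(ddof=1)
        sd_an = e.dh_sd_analytic(cand, alpha, gmap)
        # SE of a sample SD ~ sd / sqrt(2 n)
        assert sd_an == pytest.approx(sd_mc, abs=3 * sd_mc / np.sqrt(2 * n))


class TestEmbvMc:
    def test_homozygote_equals_gebv_with_zero_se(self, small_map, rng):
        hap = rng.integers(0, 2, small_map.n_loci).astype(np.uint8)
        cand = e.PhasedGenotype(hap, hap.copy())
        alpha = rng.gamma(1.66, 0.4, small_map.n_loci)
        score, reps, se = e.embv_mc(cand, alpha, small_map, 10, rng=rng)
        assert score == pytest.approx(e.gebv(cand.dosage[None], alpha)[0])
        assert se == 0.0

    def test_ng_one_recovers_gebv(self, rng):
        gmap = toy_map([10.0, 40.0, 80.0])
        cand = e.PhasedGenotype(np.array([1, 0, 1], np.uint8),
                                np.array([0, 1, 0], np.uint8))
        alpha = np.array([0.5, 0.5, 0.5])
        score, _, se = e.embv_mc(cand, alpha, gmap, 1, se_tol=0.005,
                                 max_reps=400_000, rng=rng)
        assert score == pytest.approx(e.gebv(cand.dosage[None], alpha)[0],
                                      abs=3 * max(se, 0.005))

    def test_single_het_locus_ng2_closed_form(self, rng):
        gmap = toy_map([50.0])
        cand = e.PhasedGenotype(np.array([1], np.uint8), np.array([0], np.uint8))
        score, _, se = e.embv_mc(cand, np.array([1.0]), gmap, 2, se_tol=0.004,
                                 max_reps=400_000, rng=rng)
        assert score == pytest.approx(1.5, abs=3 * se)

    def test_invalid_arguments_rejected(self, small_map, rng):
        cand = e.PhasedGenotype(np.zeros(small_map.n_loci, np.uint8),
                                np.ones(small_map.n_loci, np.uint8))
        alpha = np.ones(small_map.n_loci)
        with pytest.raises(ConfigError):
            e.embv_mc(cand, alpha, small_map, 0, rng=rng)
        with pytest.raises(ConfigError):
            e.embv_mc(cand, alpha, small_map, 5, min_reps=1, rng=rng)

    def test_determinism_with_seeded_stream(self, small_map):
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(5)
        hap1 = np.tile([1, 0], small_map.n_loci // 2).astype(np.uint8)
        hap2 = 1 - hap1
        cand = e.PhasedGenotype(hap1, hap2)
        alpha = np.full(small_map.n_loci, 0.1)
        out_a = e.embv_mc(cand, alpha, small_map, 5, rng=rng_a)
        out_b = e.embv_mc(cand, alpha, small_map, 5, rng=rng_b)
        assert out_a == out_b

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        # 8 linked het loci on two chromosomes, exact expectation by
        # enumeration of all 256 gamete classes
        gmap = toy_map([5, 20, 33, 60, 10, 42, 55, 80],
                       chrom=[0, 0, 0, 0, 1, 1, 1, 1])
        cand = e.PhasedGenotype(np.array([1, 0, 1, 0, 1, 1, 0, 1], np.uint8),
                                np.array([0, 1, 0, 1, 0, 0, 1, 0], np.uint8))
        alpha = np.array([0.7, 1.1, 0.4, 0.9, 1.3, 0.2, 0.8, 0.6])
        ng = 5
        values, probs = enumerate_dh_distribution(cand, alpha, gmap)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        exact = exact_expected_max(values, probs, ng)
        score, _, se = e.embv_mc(cand, alpha, gmap, ng, se_tol=0.003,
                                 max_reps=1_000_000, rng=rng)
        assert score == pytest.approx(exact, abs=3 * se)


class TestEmbvNormal:
    def test_degenerate_cases_equal_gebv(self, small_map, rng):
        hap = rng.integers(0, 2, small_map.n_loci).astype(np.uint8)
        homo = e.PhasedGenotype(hap, hap.copy())
        alpha = rng.gamma(1.66, 0.4, small_map.n_loci)
        g = e.gebv(homo.dosage[None], alpha)[0]
        assert e.embv_normal(homo, alpha, small_map, 10) == pytest.approx(g)
        het = e.PhasedGenotype(hap, (1 - hap).astype(np.uint8))
        g_het = e.gebv(het.dosage[None], alpha)[0]
        assert e.embv_normal(het, alpha, small_map, 1) == pytest.approx(g_het)

    def test_agrees_with_monte_carlo_for_many_het_loci(self, standard_map, rng):
        hap1 = rng.integers(0, 2, standard_map.n_loci).astype(np.uint8)
        hap2 = rng.integers(0, 2, standard_map.n_loci).astype(np.uint8)
        cand = e.PhasedGenotype(hap1, hap2)
        alpha = rng.gamma(1.66, 0.4, standard_map.n_loci) * 0.05
        ng = 10
        approx = e.embv_normal(cand, alpha, standard_map, ng)
        score, _, se = e.embv_mc(cand, alpha, standard_map, ng, se_tol=0.005,
                                 max_reps=200_000, rng=rng)
        sigma = e.dh_sd_analytic(cand, alpha, standard_map)
        # documented tolerance: normality error bounded by 5% of sigma_i
        assert abs(approx - score) <= 0.05 * sigma + 3 * se


class TestEmbvInvariants:
    def test_embv_non_decreasing_in_ng(self, rng):
        gmap = toy_map([10, 30, 50, 70, 90])
        cand = e.PhasedGenotype(np.array([1, 0, 1, 0, 1], np.uint8),
                                np.array([0, 1, 0, 1, 0], np.uint8))
        alpha = np.full(5, 0.6)
        scores = []
        ses = []
        for ng in (1, 2, 5, 10, 100):
            s, _, se = e.embv_mc(cand, alpha, gmap, ng, se_tol=0.004,
                                 max_reps=400_000, rng=rng)
            scores.append(s)
            ses.append(max(se, 0.004))
        for i in range(len(scores) - 1):
            assert scores[i + 1] >= scores[i] - 3 * (ses[i] + ses[i + 1])

    def test_phase_swap_symmetry(self, rng):
        gmap = toy_map([10, 30, 50, 70])
        h1 = np.array([1, 0, 1, 1], np.uint8)
        h2 = np.array([0, 1, 0, 0], np.uint8)
        a = e.PhasedGenotype(h1, h2)
        b = e.PhasedGenotype(h2.copy(), h1.copy())
        alpha = np.array([0.9, 0.4, 1.1, 0.3])
        part = e.partition_haplotypes(gmap, 2)
        assert e.gebv(a.dosage[None], alpha)[0] == e.gebv(b.dosage[None], alpha)[0]
        assert e.ohv(a.haps[None], alpha, part)[0] == pytest.approx(
            e.ohv(b.haps[None], alpha, part)[0])
        assert e.dh_sd_analytic(a, alpha, gmap) == pytest.approx(
            e.dh_sd_analytic(b, alpha, gmap))
        sa, _, se_a = e.embv_mc(a, alpha, gmap, 6, se_tol=0.005,
                                max_reps=400_000, rng=rng)
        sb, _, se_b = e.embv_mc(b, alpha, gmap, 6, se_tol=0.005,
                                max_reps=400_000, rng=rng)
        assert sa == pytest.approx(sb, abs=3 * (se_a + se_b))


class TestCriterionScores:
    def test_metadata_presence_rules(self):
        with pytest.raises(DataError):
            e.CriterionScores("GEBV", np.zeros(3), ng=5)
        with pytest.raises(DataError):
            e.CriterionScores("EMBV", np.zeros(3))
        with pytest.raises(DataError):
            e.CriterionScores("OHV", np.zeros(3))
        e.CriterionScores("OHV", np.zeros(3), ns_per_chrom=2)
        e.CriterionScores("EMBV", np.zeros(3), ng=5)
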