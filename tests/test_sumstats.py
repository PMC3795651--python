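import math

import numpy as np
import pytest

from msatpop import (HaplotypeAlignment, LocusSpec, expected_het, fis,
                     gtest_binomial, hwe_test, ld_test, mtdna_stats,
                     null_allele_scan, observed_het, summary_vector)
from msatpop.coalsim import DemographicModel, SimSettings, simulate_dataset
from msatpop.core_io import default_loci
from msatpop.sumstats import SUMMARY_STAT_NAMES

from conftest import make_gm

WIDE = LocusSpec("w", motif_bp=1, min_len=100, max_len=200, mu=0.0, p_gsm=0.0)


def hw_locus_gm(freqs, n, seed, n_loci=1):
    """Multi-locus dataset drawn exactly under Hardy-Weinberg."""
    rng = np.random.default_rng(seed)
    alleles = 100 + np.arange(len(freqs))
    calls = rng.choice(alleles, size=(n, n_loci, 2), p=freqs)
    return make_gm([[tuple(calls[i, j]) for j in range(n_loci)]
                    for i in range(n)], locus=WIDE)


class TestHeterozygosity:
    def test_monomorphic_he_is_zero(self):
        assert expected_het({120: 1.0}, 40) == 0.0

    def test_unbiased_he_matches_arithmetic(self):
        # (40/39) * (1 - (0.25 + 0.09 + 0.04)) = 0.635897...
        assert expected_het([0.5, 0.3, 0.2], 40) == pytest.approx(
            40 / 39 * 0.62, abs=1e-12)

    def test_too_few_copies_rejected(self):
        with pytest.raises(ValueError):
            expected_het([1.0], 1)

    def test_frequencies_must_normalize(self):
        with pytest.raises(ValueError):
            expected_het([0.5, 0.4], 10)

    def test_observed_het_direct_count(self):
        gm = make_gm([(100, 101)] * 30 + [(100, 100)] * 33, locus=WIDE)
        ho, overall = observed_het(gm)
        assert overall == pytest.approx(30 / 63)

    def test_all_homozygotes_ho_zero(self):
        gm = make_gm([(100, 100), (101, 101)], locus=WIDE)
        assert observed_het(gm)[1] == 0.0

    def test_fixture_he_in_target_band(self, ti_fixture):
        assert 0.48 <= summary_vector(ti_fixture)[0] <= 0.52


class TestFis:
    def test_zero_when_ho_equals_he(self):
        # the overall deficit heuristic: Ho/He = 0.472/0.501 -> 0.0579
        assert 1 - 0.472 / 0.501 == pytest.approx(0.0579, abs=5e-4)

    def test_random_mating_fis_near_zero(self):
        vals = []
        for seed in range(60):
            gm = hw_locus_gm([0.5, 0.3, 0.2], 63, seed, n_loci=4)
            vals.append(fis(gm, n_perm=0)[2])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 0.01

    def test_heterozygote_deficit_detected(self):
        # 80% homozygotes at a locus with two equifrequent alleles
        gm = make_gm([(100, 100)] * 25 + [(101, 101)] * 25
                     + [(100, 101)] * 13, locus=WIDE)
        per_wc, per_naive, overall, naive, test = fis(gm, n_perm=400,
                                                      rng=1)
        assert overall > 0.5
        assert test.p_value < 0.01

    def test_monomorphic_locus_excluded(self):
        gm = make_gm([[(100, 100), (100, 101)], [(100, 100), (101, 101)]],
                     locus=WIDE)
        per_wc, *_ = fis(gm, n_perm=0)
        assert math.isnan(per_wc[0])
        assert not math.isnan(per_wc[1])


class TestHweTest:
    def test_perfect_hwe_large_p(self):
        gm = make_gm([(100, 100)] * 25 + [(100, 101)] * 50
                     + [(101, 101)] * 25, locus=WIDE)
        assert hwe_test(gm, 0, n_reps=500, rng=0).p_value > 0.2

    def test_all_homozygotes_tiny_p(self):
        gm = make_gm([(100, 100)] * 30 + [(101, 101)] * 30, locus=WIDE)
        assert hwe_test(gm, 0, n_reps=2000, rng=0).p_value < 0.001

    def test_monomorphic_p_one(self):
        gm = make_gm([(100, 100)] * 5, locus=WIDE)
        assert hwe_test(gm, 0).p_value == 1.0

    def test_pvalues_uniform_under_null(self):
        from scipy import stats
        ps = []
        for seed in range(200):
            gm = hw_locus_gm([0.45, 0.35, 0.2], 50, 10_000 + seed)
            ps.append(hwe_test(gm, 0, n_reps=250, rng=seed).p_value)
        # discrete MC p-values are conservative; KS at a loose level
        assert stats.kstest(ps, "uniform").pvalue > 0.001
        assert np.mean(np.asarray(ps) < 0.05) < 0.12


class TestLdTest:
    def test_duplicated_locus_detected(self):
        rng = np.random.default_rng(3)
        col = rng.choice([100, 101, 102], size=(40, 2)).tolist()
        gm = make_gm([[tuple(c), tuple(c)] for c in col], locus=WIDE)
        assert ld_test(gm, (0, 1), n_perm=500, rng=0).p_value < 0.01

    def test_too_few_individuals_flagged_na(self):
        gm = make_gm([[(100, 101), (100, 101)]] * 3, locus=WIDE)
        assert math.isnan(ld_test(gm, (0, 1)).p_value)

    def test_independent_loci_calibrated(self):
        hits = 0
        n_pairs = 120
        for seed in range(n_pairs):
            gm = hw_locus_gm([0.5, 0.3, 0.2], 50, 20_000 + seed, n_loci=2)
            r = ld_test(gm, (0, 1), n_perm=200, rng=seed)
            hits += r.p_value < 0.05
        # expected ~5%; MC-discreteness keeps it conservative
        assert hits / n_pairs < 0.11


class TestNullAlleleScan:
    def test_monomorphic_never_flagged(self):
        gm = make_gm([(100, 100)] * 30, locus=WIDE)
        assert null_allele_scan(gm, n_reps=200, rng=0)[0]["flag"] is False

    def test_hw_calibration(self):
        flags = 0
        n = 100
        for seed in range(n):
            gm = hw_locus_gm([0.5, 0.3, 0.2], 63, 30_000 + seed)
            flags += null_allele_scan(gm, n_reps=300, rng=seed)[0]["flag"]
        assert flags / n < 0.11

    def test_planted_homozygote_excess_flagged(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([100, 101, 102], size=(63, 2),
                           p=[0.5, 0.3, 0.2])
        het = calls[:, 0] != calls[:, 1]
        mask = het & (rng.random(63) < 0.5)
        calls[mask, 1] = calls[mask, 0]
        gm = make_gm([tuple(c) for c in calls], locus=WIDE)
        out = null_allele_scan(gm, n_reps=500, rng=1)[0]
        assert out["flag"] and out["z"] > 0


class TestGTest:
    def test_null_proportion_gives_zero_g(self):
        r = gtest_binomial(5, 100, 0.05)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_excess_flags_departure(self):
        r = gtest_binomial(15, 100, 0.05)
        assert r.statistic == pytest.approx(14.06, abs=0.01)
        assert r.p_value < 0.005

    @pytest.mark.parametrize("k,n,p0", [(1, 0, 0.5), (-1, 10, 0.5),
                                        (5, 10, 0.0)])
    def test_invalid_inputs(self, k, n, p0):
        with pytest.raises(ValueError):
            gtest_binomial(k, n, p0)


class TestMtdna:
    def test_identical_sequences(self):
        aln = HaplotypeAlignment(["a", "b", "c"], ["ACGT"] * 3)
        r = mtdna_stats(aln)
        assert (r.segregating_sites, r.haplotype_diversity,
                r.nucleotide_diversity) == (0, 0.0, 0.0)

    def test_two_haplotypes_61_2(self):
        seqs = ["AAAA"] * 61 + ["AAAT"] * 2
        r = mtdna_stats(HaplotypeAlignment([f"s{i}" for i in range(63)],
                                           seqs))
        expect = 63 / 62 * (1 - (61 / 63) ** 2 - (2 / 63) ** 2)
        assert r.haplotype_diversity == pytest.approx(expect, abs=1e-12)
        assert r.haplotype_diversity == pytest.approx(0.0625, abs=5e-4)

    def test_pi_equals_h_times_diffs_over_length(self):
        # two haplotypes at 11 of L sites: pi = H * 11 / L exactly
        L, diffs, n, minor = 550, 11, 63, 5
        base = "A" * L
        alt = "T" * diffs + "A" * (L - diffs)
        aln = HaplotypeAlignment([f"s{i}" for i in range(n)],
                                 [base] * (n - minor) + [alt] * minor)
        r = mtdna_stats(aln)
        assert r.segregating_sites == diffs
        assert r.nucleotide_diversity == pytest.approx(
            r.haplotype_diversity * diffs / L, rel=1e-9)

    def test_order_invariance(self):
        seqs = ["AAAA"] * 3 + ["AATT"] * 2
        a = mtdna_stats(HaplotypeAlignment(list("abcde"), seqs))
        b = mtdna_stats(HaplotypeAlignment(list("edcba"), seqs[::-1]))
        assert a.haplotype_diversity == b.haplotype_diversity
        assert a.nucleotide_diversity == b.nucleotide_diversity

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeAlignment(["a", "b"], ["ACGT", "ACG"])


class TestSummaryVector:
    def test_monomorphic_semantics(self):
        gm = make_gm([[(100, 100), (102, 102)]] * 4, locus=WIDE)
        v = dict(zip(SUMMARY_STAT_NAMES, summary_vector(gm)))
        assert v["he_mean"] == 0.0
        assert v["ho_mean"] == 0.0
        assert v["na_mean"] == 1.0
        assert v["sizevar_mean"] == 0.0
        assert v["mratio_mean"] == 1.0

    def test_length_constant_and_deterministic(self, ti_fixture):
        v1 = summary_vector(ti_fixture)
        v2 = summary_vector(ti_fixture)
        assert v1.shape == (len(SUMMARY_STAT_NAMES),)
        assert np.array_equal(v1, v2)

    def test_he_invariant_to_allele_relabeling(self):
        gm1 = make_gm([(100, 101), (101, 102), (100, 100)], locus=WIDE)
        relabel = {100: 150, 101: 120, 102: 110}
        gm2 = make_gm([(relabel[a], relabel[b])
                       for a, b in [(100, 101), (101, 102), (100, 100)]],
                      locus=WIDE)
        assert summary_vector(gm1)[0] == pytest.approx(
            summary_vector(gm2)[0])

    def test_fast_path_agrees_with_genotype_path(self, scenario_c):
        from msatpop.sumstats import summaries_from_tips
        from msatpop.coalsim import simulate_tip_sizes
        loci = list(scenario_c.loci)
        tips = simulate_tip_sizes(scenario_c.model, loci, 63, 99, "island")
        gm = simulate_dataset(scenario_c.model, loci,
                              SimSettings(63, 99, sample_deme="island"))
        np.testing.assert_allclose(summaries_from_tips(tips, 2),
                                   summary_vector(gm), rtol=1e-12)
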