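import math

import numpy as np
import pytest

from msatpop import (DemographicModel, FounderEvent, LocusSpec, SimSettings,
                     mutate_microsat, pop_size_at, simulate_dataset,
                     simulate_genealogy)
from msatpop.coalsim import compile_epochs, simulate_tip_sizes
from msatpop.core_io import default_loci
from msatpop.sumstats import summaries_from_tips

CONST = DemographicModel(100, 100, 1e7, 1.0)


class TestPopSizeAt:
    MODEL = DemographicModel(271, 10522, 3155, 1.0)

    def test_present_size(self):
        assert pop_size_at(self.MODEL, 0.0) == pytest.approx(271)

    def test_ancestral_size_beyond_change(self):
        assert pop_size_at(self.MODEL, 3155.0) == pytest.approx(10522)
        assert pop_size_at(self.MODEL, 1e6) == pytest.approx(10522)

    def test_midpoint_is_geometric_mean(self):
        assert pop_size_at(self.MODEL, 3155 / 2) == pytest.approx(
            math.sqrt(271 * 10522), rel=1e-9)
        assert pop_size_at(self.MODEL, 3155 / 2) == pytest.approx(1689, abs=1)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pop_size_at(self.MODEL, -1.0)


class TestEpochStacking:
    def test_island_trajectory_layers(self):
        model = DemographicModel(500, 10522, 3155, 1.0,
                                 founder_event=FounderEvent(15, 16, 271))
        starts, sizes, rates = compile_epochs(model, "island")

        def n_at(t):
            j = int(np.searchsorted(starts, t, side="right")) - 1
            return sizes[j] * math.exp(rates[j] * (t - starts[j]))

        assert n_at(0.0) == pytest.approx(271)
        assert n_at(14.9) == pytest.approx(271)
        assert n_at(15.5) == pytest.approx(16)
        # after the transfer, lineages sit on the source trajectory
        assert n_at(16.0) == pytest.approx(pop_size_at(model, 16.0), rel=1e-9)
        assert n_at(5000.0) == pytest.approx(10522)

    def test_island_requires_founder_event(self):
        with pytest.raises(ValueError):
            compile_epochs(DemographicModel(500, 10522, 3155, 1.0), "island")


class TestGenealogy:
    def test_single_copy_no_coalescence(self):
        g = simulate_genealogy(CONST, SimSettings(1, 1, sample_deme="source"),
                               n_copies=1)[0]
        assert g.total_branch_length == 0.0 and g.tmrca == 0.0

    def test_pairwise_coalescence_time_2n(self):
        gs = simulate_genealogy(CONST, SimSettings(1, 42,
                                                   sample_deme="source"),
                                n_loci=4000, n_copies=2)
        t2 = np.array([g.tmrca for g in gs])
        se = t2.std(ddof=1) / math.sqrt(len(t2))
        assert abs(t2.mean() - 200.0) < 3 * se

    def test_tmrca_4n_scaling(self):
        n = 10
        gs = simulate_genealogy(CONST, SimSettings(5, 43,
                                                   sample_deme="source"),
                                n_loci=2500)
        tm = np.array([g.tmrca for g in gs])
        expect = 4 * 100 * (1 - 1 / n)
        se = tm.std(ddof=1) / math.sqrt(len(tm))
        assert abs(tm.mean() - expect) < 3 * se

    def test_ultrametric_root_last(self):
        g = simulate_genealogy(CONST, SimSettings(10, 44,
                                                  sample_deme="source"))[0]
        assert np.all(g.times[:g.n_tips] == 0.0)
        internal = g.times[g.n_tips:]
        assert np.all(np.diff(internal) > 0)
        assert g.parent[g.root] == -1

    def test_time_rescaling_matches_stepped_hazard(self):
        """Pairwise coalescence under exponential N(t) agrees with a
        brute-force per-generation Bernoulli-hazard simulator."""
        model = DemographicModel(50, 5000, 400, 1.0)
        gs = simulate_genealogy(model, SimSettings(1, 7,
                                                   sample_deme="source"),
                                n_loci=4000, n_copies=2)
        fast = np.array([g.tmrca for g in gs])

        rng = np.random.default_rng(7)
        brute = []
        for _ in range(4000):
            t = 0
            while True:
                if rng.random() < 1.0 / (2.0 * pop_size_at(model, t + 0.5)):
                    brute.append(t + rng.random())
                    break
                t += 1
        brute = np.array(brute)
        se = math.hypot(fast.std(ddof=1) / math.sqrt(len(fast)),
                        brute.std(ddof=1) / math.sqrt(len(brute)))
        assert abs(fast.mean() - brute.mean()) < 3.5 * se


class TestMutation:
    def test_tiny_tree_keeps_root_allele(self):
        locus = LocusSpec("z", mu=0.0)
        g = simulate_genealogy(CONST, SimSettings(5, 3,
                                                  sample_deme="source"))[0]
        sizes = mutate_microsat(g, locus, np.random.default_rng(0))
        assert np.all(sizes == sizes[0])
        assert locus.min_len <= sizes[0] <= locus.max_len

    def test_gsm_inflates_step_variance_geometrically(self):
        """Var(tip - tip) scales with E[step^2]; for Geometric(1-P) steps
        E[k^2] = (1+P)/(1-P)^2, so P=0.22 should double the strict-SMM
        variance (ratio 2.005)."""
        n_rep = 4000
        deep = DemographicModel(500, 500, 1e7, 1.0)
        out = {}
        for p in (0.0, 0.22):
            loci = [LocusSpec(f"m{i}", motif_bp=2, min_len=20, max_len=420,
                              mu=2e-4, p_gsm=p) for i in range(4)]
            diffs = []
            for r in range(n_rep // 4):
                tips = simulate_tip_sizes(deep, loci, 1, 900_000 + r,
                                          "source")
                diffs.extend(((tips[0] - tips[1]) / 2.0) ** 2)
            out[p] = np.mean(diffs)
        ratio = out[0.22] / out[0.0]
        assert 1.6 < ratio < 2.5

    def test_alleles_respect_reflecting_bounds(self, scenario_c):
        tips = simulate_tip_sizes(scenario_c.model, list(scenario_c.loci),
                                  63, 123, "island")
        assert tips.min() >= 20 and tips.max() <= 40
        assert np.all(tips % 2 == 0)


class TestSimulateDataset:
    def test_seed_determinism(self, scenario_c):
        loci = list(scenario_c.loci)
        s = SimSettings(20, 77, sample_deme="island")
        a = simulate_dataset(scenario_c.model, loci, s)
        b = simulate_dataset(scenario_c.model, loci, s)
        assert np.array_equal(a.calls, b.calls)

    def test_different_seeds_differ(self, scenario_c):
        loci = list(scenario_c.loci)
        a = simulate_dataset(scenario_c.model, loci,
                             SimSettings(20, 77, sample_deme="island"))
        b = simulate_dataset(scenario_c.model, loci,
                             SimSettings(20, 78, sample_deme="island"))
        assert not np.array_equal(a.calls, b.calls)

    def test_smm_equilibrium_heterozygosity(self):
        """Constant-N strict SMM: He = 1 - 1/sqrt(1 + 2 theta') with
        theta' = 4 N mu (wide bounds so reflection is negligible)."""
        N, mu = 500, 5e-4
        theta = 4 * N * mu
        expect = 1 - 1 / math.sqrt(1 + 2 * theta)
        model = DemographicModel(N, N, 1e7, 1.0)
        loci = [LocusSpec(f"e{i}", motif_bp=2, min_len=20, max_len=220,
                          mu=mu, p_gsm=0.0) for i in range(10)]
        hes = [summaries_from_tips(
            simulate_tip_sizes(model, loci, 50, 5000 + r, "source"))[0]
            for r in range(400)]
        assert abs(np.mean(hes) - expect) < 0.02
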