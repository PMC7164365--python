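"""Generators: birth-death/BiSSE trees, Mk and OU traits, occurrences,
abundance samples.  Stochastic checks use seeded Monte-Carlo bands."""

import numpy as np
import pytest
from scipy.linalg import expm

import terebra as tb
from terebra import BisseParams, SimConfig


class TestBdTree:
    def test_yule_crown_expectation(self):
        # crown process with 2 starting lineages: E[tips] = 2 exp(lam T)
        lam, T, reps = 0.2, 5.0, 800
        tips = np.array([
            tb.simulate_bd_tree(lam, 0.0, SimConfig(seed=s, crown_age=T)).n_tips
            for s in range(reps)])
        expected = 2 * np.exp(lam * T)
        se = tips.std(ddof=1) / np.sqrt(reps)
        assert abs(tips.mean() - expected) < 4 * se + 0.05

    def test_pure_birth_is_ultrametric_binary(self):
        t = tb.simulate_bd_tree(0.3, 0.0, SimConfig(seed=3, n_taxa=40))
        assert t.is_ultrametric() and t.is_binary()
        assert t.n_tips == 40

    def test_seed_determinism(self):
        cfg = SimConfig(seed=11, n_taxa=25, sampling_fraction=0.5)
        t1 = tb.simulate_bd_tree(0.4, 0.1, cfg)
        t2 = tb.simulate_bd_tree(0.4, 0.1, cfg)
        assert tb.write_newick(t1) == tb.write_newick(t2)

    def test_sampling_reduces_tips(self):
        full = tb.simulate_bd_tree(0.3, 0.0, SimConfig(seed=5, crown_age=12))
        sub = tb.simulate_bd_tree(
            0.3, 0.0, SimConfig(seed=5, crown_age=12, sampling_fraction=0.3))
        assert sub.n_tips <= full.n_tips

    def test_unreachable_stop_errors(self):
        with pytest.raises(tb.SimulationError):
            tb.simulate_bd_tree(
                0.01, 2.0, SimConfig(seed=1, n_taxa=500, retry_cap=5))


class TestBisseSim:
    def test_no_transition_monomorphic(self):
        _, states, _ = tb.simulate_bisse(
            BisseParams(0.3, 0.3, 0.0, 0.0, 0.0, 0.0),
            SimConfig(seed=2, n_taxa=30), root_state=0)
        assert set(states.values()) == {0}

    def test_neutral_states_reach_stationary_frequency(self):
        # lam0=lam1, mu0=mu1: tip frequencies follow the q stationary law
        p = BisseParams(0.3, 0.3, 0.0, 0.0, 0.06, 0.02)
        pi1 = p.stationary_root_distribution()[1]
        ones = total = 0
        for s in range(25):
            _, states, _ = tb.simulate_bisse(p, SimConfig(seed=s, n_taxa=80))
            vals = list(states.values())
            ones += sum(vals)
            total += len(vals)
        freq = ones / total
        assert abs(freq - pi1) < 0.12  # tips are correlated; generous band

    def test_history_consistent_with_tips(self):
        tree, states, hist = tb.simulate_bisse(
            BisseParams(0.25, 0.35, 0.05, 0.05, 0.05, 0.05),
            SimConfig(seed=7, n_taxa=50))
        assert hist.tip_regimes() == states
        for v in range(tree.n_nodes):
            if v != tree.root:
                assert sum(d for _, d in hist.paintings[v]) == pytest.approx(
                    tree.lengths[v], rel=1e-9, abs=1e-12)


class TestMk:
    def test_zero_rate_keeps_root_state(self, yule100):
        states, _ = tb.simulate_mk(yule100, 0.0, 0.0, 1, seed=1)
        assert set(states.values()) == {1}

    def test_transition_probability_matches_matrix_exponential(self):
        # one cherry, branch length 2: tip state distribution from root
        t = tb.read_newick("(A:2,B:2);")
        q01, q10 = 0.15, 0.05
        Q = np.array([[-q01, q01], [q10, -q10]])
        P = expm(Q * 2.0)
        reps = 8000
        rng_states = [tb.simulate_mk(t, q01, q10, 0, seed=s)[0]["A"]
                      for s in range(reps)]
        freq1 = np.mean(rng_states)
        se = np.sqrt(P[0, 1] * (1 - P[0, 1]) / reps)
        assert abs(freq1 - P[0, 1]) < 4 * se

    def test_expected_changes_poisson_limit(self):
        # small q t: E[#changes] ~ q t on a single branch
        t = tb.read_newick("(A:1,B:1);")
        q = 0.02
        changes = []
        for s in range(4000):
            _, hist = tb.simulate_mk(t, q, q, 0, seed=s)
            a = t.tip_index()["A"]
            changes.append(len(hist.paintings[a]) - 1)
        mean = np.mean(changes)
        assert abs(mean - q * 1.0) < 4 * np.std(changes) / np.sqrt(4000)

    def test_negative_rate_rejected(self, yule100):
        with pytest.raises(ValueError):
            tb.simulate_mk(yule100, -0.1, 0.1, 0, seed=0)


class TestOu:
    def test_bm_limit_covariance(self, five_tip_tree):
        t = five_tip_tree
        paint = [None if v == t.root else [("r", t.lengths[v])]
                 for v in range(t.n_nodes)]
        pm = tb.RegimePaintedTree(t, paint)
        s2 = 1.7
        vals = tb.simulate_ou(pm, {"r": 0.0}, {"r": s2}, {"r": 0.0},
                              seed=3, n_reps=6000)
        emp = np.cov(vals.to_numpy())
        V = s2 * tb.vcv_matrix(t)
        order = [t.tip_labels.index(l) for l in vals.index]
        np.testing.assert_allclose(emp, V[np.ix_(order, order)],
                                   atol=0.35, rtol=0.1)

    def test_strong_pull_concentrates_at_optimum(self, five_tip_tree):
        t = five_tip_tree
        paint = [None if v == t.root else [("r", t.lengths[v])]
                 for v in range(t.n_nodes)]
        pm = tb.RegimePaintedTree(t, paint)
        a, s2, th = 40.0, 2.0, 7.0
        vals = tb.simulate_ou(pm, {"r": a}, {"r": s2}, {"r": th},
                              seed=4, n_reps=4000).to_numpy().ravel()
        assert abs(vals.mean() - th) < 0.01
        assert abs(vals.var() - s2 / (2 * a)) < 0.005

    def test_seed_determinism(self, single_regime_painting):
        kw = dict(alpha={"r": 0.5}, sigma2={"r": 1.0}, theta={"r": 0.0},
                  seed=9, n_reps=3)
        v1 = tb.simulate_ou(single_regime_painting, **kw)
        v2 = tb.simulate_ou(single_regime_painting, **kw)
        assert (v1 == v2).all().all()


class TestOccurrences:
    def test_zero_width_stations_inside_true_range(self):
        occ = tb.simulate_occurrences({"sp1": (10, 50)}, n_stations=30,
                                      dredge_width=0.0, seed=1)
        assert (occ["station_min_depth"] == occ["station_max_depth"]).all()
        assert occ["station_min_depth"].between(10, 50).all()

    def test_station_contains_point_of_true_range(self):
        ranges = {"a": (5, 20), "b": (100, 400)}
        occ = tb.simulate_occurrences(ranges, n_stations=20,
                                      dredge_width=50, seed=2)
        for _, row in occ.iterrows():
            lo, hi = ranges[row["species"]]
            assert row["station_min_depth"] <= hi + 0.11
            assert row["station_max_depth"] >= lo - 0.11

    def test_conservative_range_converges_into_truth(self):
        from terebra.occurrence import species_depth_range
        truth = (50, 300)
        widths = []
        for n in (3, 30, 300):
            occ = tb.simulate_occurrences({"sp": truth}, n_stations=n,
                                          dredge_width=40, seed=5)
            r = species_depth_range(
                zip(occ["station_min_depth"], occ["station_max_depth"]))
            # conservative: the estimate narrows from inside as n grows
            widths.append(r.max_depth - r.min_depth)
            assert r.min_depth >= truth[0] - 40.1
            assert r.max_depth <= truth[1] + 40.1
        assert widths[-1] >= widths[0] - 1e-9
        occ = tb.simulate_occurrences({"sp": truth}, n_stations=500,
                                      dredge_width=5, seed=6)
        r = species_depth_range(
            zip(occ["station_min_depth"], occ["station_max_depth"]))
        assert r.min_depth >= truth[0] and r.max_depth <= truth[1]

    def test_determinism_and_empty_range(self):
        o1 = tb.simulate_occurrences({"x": (1, 2)}, seed=3)
        o2 = tb.simulate_occurrences({"x": (1, 2)}, seed=3)
        assert o1.equals(o2)
        with pytest.raises(ValueError):
            tb.simulate_occurrences({"x": (5, 2)}, seed=3)


class TestAbundance:
    def test_uniform_saturation_gives_chao1_equal_truth(self):
        s = tb.simulate_abundance_sample(40, 100_000, "uniform", seed=1)
        sample = tb.diversity_sample_from_counts(s.to_dict())
        assert sample.f1 == 0 and sample.f2 == 0
        assert tb.chao1(sample).estimate == sample.s_obs == 40

    def test_logseries_chao1_calibration(self):
        # configured regime: moderately complete sampling of 100 species
        # (singletons/doubletons still present; see docs/methods.md)
        S, m = 100, 20_000
        ests = []
        for s in range(100):
            counts = tb.simulate_abundance_sample(S, m, "logseries",
                                                  shape=0.95, seed=s)
            ests.append(tb.chao1(
                tb.diversity_sample_from_counts(counts.to_dict())).estimate)
        assert abs(np.mean(ests) - S) / S < 0.10

    def test_counts_sum_and_determinism(self):
        c1 = tb.simulate_abundance_sample(30, 500, seed=7)
        c2 = tb.simulate_abundance_sample(30, 500, seed=7)
        assert c1.sum() == 500 and c1.equals(c2)
        with pytest.raises(ValueError):
            tb.simulate_abundance_sample(30, 0, seed=7)
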