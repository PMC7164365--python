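"""Mk estimation, stochastic character maps, and the BM/OU suite."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import multivariate_normal

import terebra as tb
from terebra.regimes import (OU_MODELS, MkModel, _sample_bridge_flips,
                             ancestral_marginals, fit_mk, fit_ou_model,
                             fit_ou_suite, mk_loglik, ou_loglik,
                             stochastic_map)


def single_regime(tree, label="r"):
    paint = [None if v == tree.root else [(label, tree.lengths[v])]
             for v in range(tree.n_nodes)]
    return tb.RegimePaintedTree(tree, paint)


class TestMk:
    def test_two_tip_closed_form(self):
        t = tb.read_newick("(A:0.8,B:1.3);")
        q = 0.21
        Q = np.array([[-q, q], [q, -q]])
        states = {"A": 0, "B": 1}
        direct = 0.0
        for r in (0, 1):
            pa = expm(Q * 0.8)[r, 0]
            pb = expm(Q * 1.3)[r, 1]
            direct += 0.5 * pa * pb
        assert mk_loglik(t, states, q) == pytest.approx(
            np.log(direct), abs=1e-12)

    def test_monomorphic_maximized_at_zero_rate(self, yule100):
        states = {l: 0 for l in yule100.tip_labels}
        lls = [mk_loglik(yule100, states, q) for q in (1e-8, 0.01, 0.1)]
        assert lls[0] == max(lls)
        fit = fit_mk(yule100, states)
        assert fit.boundary

    def test_rate_recovery_within_factor_two(self):
        hits = 0
        reps = 15
        for s in range(reps):
            tree = tb.simulate_yule_tree(0.1, 200, seed=900 + s)
            states, _ = tb.simulate_mk(tree, 0.05, 0.05, 0, seed=s)
            if len(set(states.values())) < 2:
                hits += 1  # monomorphic draws excluded from the check
                continue
            q_hat = fit_mk(tree, states).q
            hits += 0.5 * 0.05 <= q_hat <= 2 * 0.05
        assert hits >= int(0.8 * reps)

    def test_mcmc_mode_reports_posterior(self):
        tree = tb.simulate_yule_tree(0.1, 80, seed=31)
        states, _ = tb.simulate_mk(tree, 0.08, 0.08, 0, seed=2)
        fit = fit_mk(tree, states, method="MCMC", seed=5,
                     mcmc_iter=300, mcmc_thin=10)
        assert fit.posterior_draws is not None
        assert fit.posterior_mean > 0


class TestStochasticMap:
    def test_zero_rate_single_regime(self, yule100):
        states = {l: 1 for l in yule100.tip_labels}
        mk = MkModel(q=0.0)
        maps = stochastic_map(yule100, states, mk, n_maps=3, seed=1)
        for m in maps:
            for v in range(yule100.n_nodes):
                if v != yule100.root:
                    assert len(m.paintings[v]) == 1

    def test_tip_regimes_match_observations(self, yule100):
        states, _ = tb.simulate_mk(yule100, 0.05, 0.05, 0, seed=3)
        mk = fit_mk(yule100, states)
        for m in stochastic_map(yule100, states, mk, n_maps=10, seed=2):
            assert m.tip_regimes() == states

    def test_node_marginals_match_pruning_oracle(self):
        tree = tb.simulate_yule_tree(0.1, 60, seed=11)
        states, _ = tb.simulate_mk(tree, 0.05, 0.05, 0, seed=3)
        mk = fit_mk(tree, states)
        n_maps = 1500
        maps = stochastic_map(tree, states, mk, n_maps=n_maps, seed=5)
        marg = ancestral_marginals(tree, states, mk)
        freq = np.zeros(tree.n_nodes)
        for m in maps:
            for v in tree.internal_ids:
                s = (m.root_regime() if v == tree.root
                     else m.paintings[v][-1][0])
                freq[v] += s
        freq /= n_maps
        err = np.abs(freq[tree.internal_ids] - marg[tree.internal_ids, 1])
        assert err.max() < 0.05  # ~4 sigma at 1500 maps

    def test_bridge_flip_moments(self):
        # conditioned flip counts: E[N|even] = L tanh(L), E[N|odd] = L coth(L)
        rng = np.random.default_rng(0)
        L = 0.8
        same = [_sample_bridge_flips(rng, L, True) for _ in range(20000)]
        diff = [_sample_bridge_flips(rng, L, False) for _ in range(20000)]
        assert np.mean(same) == pytest.approx(L * np.tanh(L), abs=0.02)
        assert np.mean(diff) == pytest.approx(L / np.tanh(L), abs=0.02)
        assert all(n % 2 == 0 for n in same)
        assert all(n % 2 == 1 for n in diff)


class TestOuLoglik:
    def test_single_regime_matches_analytic_moments(self, five_tip_tree):
        pm = single_regime(five_tip_tree)
        a, s2 = 0.7, 1.3
        x = {"A": 4.2, "B": 5.5, "C": 6.0, "D": 4.9, "E": 5.1}
        ll, th = ou_loglik(pm, x, "OU1", alpha=a, sigma2=s2)
        t = five_tip_tree
        D = tb.patristic_distances(t)
        V = s2 / (2 * a) * np.exp(-a * D)  # stationary OU covariance
        xv = np.array([x[l] for l in t.tip_labels])
        ones = np.ones(5)
        Vi = np.linalg.inv(V)
        mu = (ones @ Vi @ xv) / (ones @ Vi @ ones)
        direct = multivariate_normal(np.full(5, mu), V).logpdf(xv)
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_bms_with_equal_rates_collapses_to_bm1(self, five_tip_tree):
        t = five_tip_tree
        paint = [None if v == t.root else
                 ([("p", t.lengths[v] / 2), ("q", t.lengths[v] / 2)]
                  if t.lengths[v] > 0 else [("p", 0.0)])
                 for v in range(t.n_nodes)]
        pm2 = tb.RegimePaintedTree(t, paint)
        x = {"A": 1.0, "B": -0.5, "C": 0.3, "D": 2.0, "E": 0.0}
        ll_bms, _ = ou_loglik(pm2, x, "BMS", sigma2={"p": 1.7, "q": 1.7})
        ll_bm1, _ = ou_loglik(single_regime(t), x, "BM1", sigma2=1.7)
        assert ll_bms == pytest.approx(ll_bm1, abs=1e-10)

    def test_ou1_small_alpha_approaches_bm1(self, five_tip_tree):
        pm = single_regime(five_tip_tree)
        x = {"A": 1.0, "B": -0.5, "C": 0.3, "D": 2.0, "E": 0.0}
        ll_bm, _ = ou_loglik(pm, x, "BM1", sigma2=0.9)
        ll_ou, _ = ou_loglik(pm, x, "OU1", alpha=1e-8, sigma2=0.9,
                             root_mode="fixed")
        assert abs(ll_ou - ll_bm) < 1e-4

    def test_matches_simulated_moment_gaussian(self, five_tip_tree):
        t = five_tip_tree
        paint = [None if v == t.root else
                 ([("hot", t.lengths[v] * 0.4), ("cold", t.lengths[v] * 0.6)]
                  if t.lengths[v] > 0 else [("hot", 0.0)])
                 for v in range(t.n_nodes)]
        pm = tb.RegimePaintedTree(t, paint)
        alpha = {"hot": 0.9, "cold": 0.3}
        sigma2 = {"hot": 2.0, "cold": 0.8}
        theta = {"hot": 3.0, "cold": -1.0}
        sims = tb.simulate_ou(pm, alpha, sigma2, theta, seed=17,
                              n_reps=100_000,
                              root_mode="stationary").to_numpy()
        mean_hat = sims.mean(axis=1)
        cov_hat = np.cov(sims)
        x = {"A": 2.0, "B": 0.5, "C": 1.0, "D": -0.4, "E": 0.3}
        xv = np.array([x[l] for l in pm.tree.tip_labels])
        order = [list(tb.simulate_ou(pm, alpha, sigma2, theta, seed=1).index
                      ).index(l) for l in pm.tree.tip_labels]
        ll_mc = multivariate_normal(
            mean_hat[order], cov_hat[np.ix_(order, order)]).logpdf(xv)
        ll, th = ou_loglik(pm, x, "OUMVA", alpha=alpha, sigma2=sigma2,
                           root_mode="stationary")
        # evaluate at the true optima rather than the GLS profile
        from terebra.regimes import _moments
        A, Var, C, design = _moments(pm, alpha, sigma2, "OUMVA", "stationary")
        tips = pm.tree.tip_ids
        M = pm.tree.mrca_matrix()
        V = Var[M] * (A[tips][:, None] / A[M]) * (A[tips][None, :] / A[M])
        np.fill_diagonal(V, Var[tips])
        W = C[tips]
        tvec = np.array([theta[d[6:-1]] for d in design])
        ll_true = multivariate_normal(W @ tvec, V).logpdf(xv)
        assert ll_true == pytest.approx(ll_mc, abs=0.05)

    def test_nesting_at_mle(self):
        tree = tb.simulate_yule_tree(0.1, 80, seed=51)
        states, hist = tb.simulate_mk(tree, 0.05, 0.05, 0, seed=4)
        x = tb.simulate_ou(hist, {0: 0.4, 1: 0.4}, {0: 1.0, 1: 1.0},
                           {0: 2.0, 1: 2.0}, seed=6)[0]
        fits = {}
        chain = ["OU1", "OUM", "OUMV", "OUMVA"]
        prev = None
        for m in chain:
            extra = []
            if prev is not None:
                extra = [(fits[prev].params.get("alpha", 0.1),
                          fits[prev].params["sigma2"])]
            fits[m] = fit_ou_model(hist, x, m, n_starts=2, seed=1,
                                   compute_hessian=False,
                                   extra_starts=extra)
            if prev is not None:
                assert fits[m].loglik >= fits[prev].loglik - 1e-4
            prev = m
        bm1 = fit_ou_model(hist, x, "BM1", n_starts=2, seed=1,
                           compute_hessian=False)
        bms = fit_ou_model(hist, x, "BMS", n_starts=2, seed=1,
                           compute_hessian=False,
                           extra_starts=[(0.0, bm1.params["sigma2"])])
        assert bms.loglik >= bm1.loglik - 1e-4


class TestOuSuite:
    def test_two_bm_and_five_ou_variants(self):
        assert len(OU_MODELS) == 7
        bm = [m for m in OU_MODELS if m.startswith("BM")]
        ou = [m for m in OU_MODELS if m.startswith("OU")]
        assert len(bm) == 2 and len(ou) == 5

    def test_parameter_counts_scale_with_regimes(self, five_tip_tree):
        pm = single_regime(five_tip_tree)
        x = {"A": 1.0, "B": -0.5, "C": 0.3, "D": 2.0, "E": 0.7}
        k = {m: fit_ou_model(pm, x, m, n_starts=1, seed=0,
                             compute_hessian=False).k
             for m in ("BM1", "OU1")}
        assert k["BM1"] == 2 and k["OU1"] == 3

    def test_suite_summary_accounting(self):
        tree = tb.simulate_yule_tree(0.1, 50, seed=71)
        states, hist = tb.simulate_mk(tree, 0.06, 0.06, 0, seed=8)
        x = tb.simulate_ou(hist, {0: 0.5, 1: 0.5}, {0: 4.0, 1: 4.0},
                           {0: 10.0, 1: 2.0}, seed=9)[0]
        mk = fit_mk(tree, states)
        maps = stochastic_map(tree, states, mk, n_maps=3, seed=10)
        res = fit_ou_suite(maps, x, models=["BM1", "OUM", "OUMVA"],
                           seed=2, n_starts=1)
        s = res["summary"]
        assert set(s["mean_weights"]) == {"BM1", "OUM", "OUMVA"}
        assert sum(s["mean_weights"].values()) == pytest.approx(1.0, abs=1e-9)
        assert s["params"]["n_used"] + s["params"]["n_flagged"] == 3
        assert len(res["per_map"]) == 3
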