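"""State-dependent diversification likelihood, fitting, model choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import terebra as tb
from terebra import BisseParams, SimConfig
from terebra.bisse import _integrate_E_impl, bisse_model_lattice
from terebra.modelsel import select_model
from terebra.tree import TreeError


def oracle_bisse_loglik(tree, states, p, f, step=1e-4):
    """Independent check: per-branch fixed-step RK4 on the full coupled
    4-component (E, D) system, no shared-E shortcut, no rescaling."""
    lam = np.array([p.lambda0, p.lambda1])
    mu = np.array([p.mu0, p.mu1])
    q = np.array([p.q01, p.q10])

    def rhs(y):
        E, D = y[:2], y[2:]
        Ej, Dj = E[::-1], D[::-1]
        dE = mu - (lam + mu + q) * E + lam * E * E + q * Ej
        dD = -(lam + mu + q) * D + q * Dj + 2 * lam * E * D
        return np.concatenate([dE, dD])

    def integrate(y, t0, t1):
        n = max(1, int(np.ceil((t1 - t0) / step)))
        h = (t1 - t0) / n
        for _ in range(n):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    ages = tree.ages()
    vals = {}
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            y = np.zeros(4)
            y[0], y[1] = 1 - f[0], 1 - f[1]
            s = states[tree.labels[v]]
            y[2 + s] = f[s]
            vals[v] = y
        else:
            ya = integrate(vals[kids[0]], ages[kids[0]], ages[v])
            yb = integrate(vals[kids[1]], ages[kids[1]], ages[v])
            y = ya.copy()
            y[2:] = ya[2:] * yb[2:] * lam
            vals[v] = y
    yr = vals[tree.root]
    E, D = yr[:2], yr[2:]
    w = D / D.sum()
    return float(np.log(w @ D) - np.log(w @ (lam * (1 - E) ** 2)))


class TestLoglik:
    def test_full_model_has_six_parameters(self):
        from terebra.bisse import _resolve_constraint
        free, _ = _resolve_constraint(None)
        assert len(free) == 6

    def test_reduces_to_yule(self, yule100):
        states = {l: 0 for l in yule100.tip_labels}
        p = BisseParams(0.1, 0.1, 0.0, 0.0, 0.0, 0.0)
        ll = tb.bisse_loglik(yule100, states, p)
        assert ll == pytest.approx(tb.yule_loglik(yule100, 0.1), abs=1e-6)

    def test_state_label_swap_symmetry(self, yule100):
        rng = np.random.default_rng(1)
        states = {l: int(rng.random() < 0.4) for l in yule100.tip_labels}
        p = BisseParams(0.12, 0.2, 0.03, 0.06, 0.04, 0.08)
        f = (0.5, 0.8)
        ll = tb.bisse_loglik(yule100, states, p, f)
        swapped = {l: 1 - s for l, s in states.items()}
        p_sw = BisseParams(0.2, 0.12, 0.06, 0.03, 0.08, 0.04)
        ll_sw = tb.bisse_loglik(yule100, swapped, p_sw, (0.8, 0.5))
        assert ll == pytest.approx(ll_sw, abs=1e-10)

    def test_matches_independent_integrator(self, five_tip_tree):
        states = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0}
        p = BisseParams(0.3, 0.5, 0.1, 0.05, 0.1, 0.2)
        f = (0.7, 0.9)
        ll = tb.bisse_loglik(five_tip_tree, states, p, f)
        ll_oracle = oracle_bisse_loglik(five_tip_tree, states, p, f)
        assert ll == pytest.approx(ll_oracle, abs=1e-5)

    def test_continuous_in_sampling_fraction(self, yule100):
        rng = np.random.default_rng(2)
        states = {l: int(rng.random() < 0.5) for l in yule100.tip_labels}
        p = BisseParams(0.15, 0.15, 0.02, 0.02, 0.03, 0.03)
        eps = 1e-5
        base = tb.bisse_loglik(yule100, states, p, (0.6, 0.6))
        up = tb.bisse_loglik(yule100, states, p, (0.6 + eps, 0.6))
        assert abs(up - base) < 1.0  # finite slope, no jump

    def test_polytomy_and_nonultrametric_rejected(self):
        poly = tb.read_newick("(A:1,B:1,C:1);")
        p = BisseParams(0.1, 0.1, 0, 0, 0.01, 0.01)
        with pytest.raises(TreeError):
            tb.bisse_loglik(poly, {"A": 0, "B": 0, "C": 1}, p)
        skew = tb.read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(TreeError):
            tb.bisse_loglik(skew, {"A": 0, "B": 0, "C": 1}, p)

    @given(lam0=st.floats(0.05, 1.0), lam1=st.floats(0.05, 1.0),
           mu0=st.floats(0.0, 0.5), mu1=st.floats(0.0, 0.5),
           q=st.floats(0.0, 0.5), f0=st.floats(0.2, 1.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_extinction_probability_stays_in_unit_interval(
            self, lam0, lam1, mu0, mu1, q, f0):
        dts = np.full(400, 50.0 / 400)
        E = _integrate_E_impl(dts, 1 - f0, 1 - f0, lam0, lam1,
                              mu0, mu1, q, q)
        assert np.all(E >= -1e-9) and np.all(E <= 1 + 1e-9)

    def test_no_extinction_full_sampling_keeps_E_zero(self):
        dts = np.full(100, 0.5)
        E = _integrate_E_impl(dts, 0.0, 0.0, 0.3, 0.5, 0.0, 0.0, 0.1, 0.1)
        np.testing.assert_allclose(E, 0.0, atol=1e-12)


class TestFitting:
    def test_lattice_spans_reported_scenarios(self):
        lattice = bisse_model_lattice()
        assert "full" in lattice
        # state-independent null: all three rate pairs constrained
        assert len(lattice["equal.all"]) == 3
        # the irreversible equal-rates scenario of the venom-gland result
        assert lattice["equal.lambda.mu.irrev"]["q10"] == 0.0

    def test_nested_model_never_beats_full(self):
        p = BisseParams(0.2, 0.2, 0.05, 0.05, 0.04, 0.04)
        tree, states, _ = tb.simulate_bisse(p, SimConfig(seed=5, n_taxa=80))
        null = tb.fit_bisse(tree, states,
                            {"lambda1": "lambda0", "mu1": "mu0",
                             "q10": "q01"}, n_starts=2, seed=1)
        assert null.k == 3
        full = tb.fit_bisse(tree, states, None, n_starts=2, seed=1,
                            extra_starts=[null.params])
        assert full.k == 6
        assert full.loglik >= null.loglik - 1e-4

    def test_constrained_fit_dominates_truth(self):
        p = BisseParams(0.25, 0.25, 0.05, 0.05, 0.03, 0.03)
        tree, states, _ = tb.simulate_bisse(p, SimConfig(seed=6, n_taxa=80))
        constraint = {"lambda1": "lambda0", "mu1": "mu0", "q10": "q01"}
        fit = tb.fit_bisse(tree, states, constraint, n_starts=2, seed=2,
                           extra_starts=[{
                               "lambda0": 0.25, "mu0": 0.05, "q01": 0.03}])
        ll_truth = tb.bisse_loglik(tree, states, p)
        assert fit.loglik >= ll_truth - 1e-4

    def test_hessian_diagnostics_available(self):
        p = BisseParams(0.3, 0.3, 0.05, 0.05, 0.05, 0.05)
        tree, states, _ = tb.simulate_bisse(p, SimConfig(seed=8, n_taxa=60))
        fit = tb.fit_bisse(tree, states,
                           {"lambda1": "lambda0", "mu1": "mu0",
                            "q10": "q01"},
                           n_starts=1, seed=0, compute_hessian=True)
        assert fit.hessian_eigenvalues is not None
        assert fit.hessian_eigenvalues.size == 3


class TestSelection:
    def test_weight_arithmetic(self):
        from terebra.modelsel import ModelFit
        a = ModelFit("a", {}, loglik=-48.0, k=2, n=50)
        b = ModelFit("b", {}, loglik=-53.0, k=2, n=50)
        res = select_model([a, b])
        assert res["decision"] == "winner"
        assert res["best_weight"] == pytest.approx(1 / (1 + np.exp(-5)))

    def test_boundary_delta_is_ambiguous(self):
        from terebra.modelsel import ModelFit
        a = ModelFit("a", {}, loglik=-50.0, k=2, n=50)
        b = ModelFit("b", {}, loglik=-50.5, k=2, n=50)
        assert select_model([a, b])["decision"] == "ambiguous"
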