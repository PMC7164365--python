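"""Time-varying birth-death diversification fits on branching times.

Six nested models of the reconstructed process with a global extant
sampling fraction f: (1) pure birth; (2) constant birth-death;
(3) exponential-in-time speciation, no extinction; (4) exponential
speciation, constant extinction; (5) constant speciation, exponential
extinction; (6) both exponential.  Rates are rate(t) = r0 exp(a t) with
t the age before the present, so r0 is the present-day rate.

The likelihood uses the single-character reduction of the state-dependent
machinery: with E(t) the probability that a lineage alive at age t leaves
no sampled descendant and G(t) = int_0^t (lambda + mu - 2 lambda E) du,
each branch contributes exp(-(G(top) - G(bottom))), each internal node a
factor lambda(age), each tip a factor f, and the likelihood is
conditioned on both crown lineages surviving to the present (divide by
(1 - E(T))^2; the root's lambda factor is dropped).  For constant rates
the classical closed forms p0/p1 are used instead of quadrature; the two
paths are algebraically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .modelsel import ModelFit, data_checksum, model_table
from .tree import PhyloTree, TreeError

__all__ = ["RateFunctionSpec", "BD_MODELS", "bd_loglik", "fit_bd_suite",
           "rates_through_time", "constant_rate_loglik"]

_EXP_BOUND = 1.0  # |exponent| bound, /Myr (an e-fold rate change per Myr)
_RATE_BOUNDS = (1e-8, 1e3)


@dataclass(frozen=True)
class RateFunctionSpec:
    """One rate through time: zero, constant, or exponential in age."""

    role: str  # "speciation" | "extinction"
    form: str  # "zero" | "constant" | "exponential"
    rate0: float = 0.0  # rate at the present
    exponent: float = 0.0  # /Myr, age measured backward from present

    def __post_init__(self):
        if self.form not in ("zero", "constant", "exponential"):
            raise ValueError(f"unknown form '{self.form}'")
        if self.rate0 < 0:
            raise ValueError("base rate must be nonnegative")

    def __call__(self, t):
        if self.form == "zero":
            return np.zeros_like(np.asarray(t, dtype=float))
        if self.form == "constant":
            return np.full_like(np.asarray(t, dtype=float), self.rate0)
        return self.rate0 * np.exp(self.exponent * np.asarray(t, dtype=float))

    @property
    def is_constant(self) -> bool:
        return self.form in ("zero", "constant") or self.exponent == 0.0


#: the six nested models: name -> (lambda form, mu form, k)
BD_MODELS = {
    "yule": ("constant", "zero", 1),
    "const_bd": ("constant", "constant", 2),
    "var_lambda": ("exponential", "zero", 2),
    "var_lambda_const_mu": ("exponential", "constant", 3),
    "const_lambda_var_mu": ("constant", "exponential", 3),
    "var_both": ("exponential", "exponential", 4),
}


def _node_ages(tree: PhyloTree):
    if not tree.is_binary():
        raise TreeError("birth-death likelihood requires a binary tree")
    if not tree.is_ultrametric():
        raise TreeError("birth-death likelihood requires an ultrametric tree")
    ages = tree.ages()
    ages[tree.tip_ids] = 0.0
    return ages


def constant_rate_loglik(tree: PhyloTree, lam: float, mu: float,
                         f: float = 1.0) -> float:
    """Closed-form constant-rate reconstructed-process log-likelihood
    (crown-conditioned), via the classical p0/p1 expressions."""
    ages = _node_ages(tree)
    T = ages[tree.root]
    x = np.sort(ages[tree.internal_ids])[::-1]

    def log_p1(t):
        t = np.asarray(t, dtype=float)
        if abs(lam - mu) < 1e-12:
            return np.log(f) - 2 * np.log1p(f * lam * t)
        r = lam - mu
        denom = f * lam + (lam * (1 - f) - mu) * np.exp(-r * t)
        return np.log(f) + 2 * np.log(abs(r)) - r * t - 2 * np.log(denom)

    def p0(t):
        if abs(lam - mu) < 1e-12:
            return 1 - f / (1 + f * lam * t)
        r = lam - mu
        denom = f * lam + (lam * (1 - f) - mu) * np.exp(-r * t)
        return 1 - f * r / denom

    inner = x[1:]  # non-root internal node ages
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll = (2 * log_p1(T) - 2 * np.log1p(-p0(T))
              + np.sum(np.log(lam) + log_p1(inner)))
    return float(ll) if np.isfinite(ll) else -np.inf


def bd_loglik(tree: PhyloTree, lam_spec: RateFunctionSpec,
              mu_spec: RateFunctionSpec, f: float = 1.0,
              rtol: float = 1e-10, atol: float = 1e-10) -> float:
    """Log-likelihood of the branching times under time-varying rates.

    Constant-rate inputs take the closed-form path automatically.
    """
    if not (0 < f <= 1):
        raise ValueError("sampling fraction must lie in (0, 1]")
    ages = _node_ages(tree)
    T = ages[tree.root]
    grid = np.linspace(0, T, 201)
    if np.any(lam_spec(grid) < 0) or np.any(mu_spec(grid) < 0):
        raise ValueError("rate evaluates negative on [0, crown age]")

    if lam_spec.is_constant and mu_spec.is_constant:
        return constant_rate_loglik(tree, float(lam_spec(0.0)),
                                    float(mu_spec(0.0)), f)

    def rhs(t, y):
        E = y[0]
        l, m = float(lam_spec(t)), float(mu_spec(t))
        return [m - (l + m) * E + l * E * E,
                l + m - 2 * l * E]

    sol = solve_ivp(rhs, (0.0, T), [1.0 - f, 0.0], dense_output=True,
                    rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"E/G integration failed: {sol.message}")

    EG = sol.sol(ages)  # (2, n_nodes) dense evaluation at every node age
    G = EG[1]
    E_T = float(sol.sol(T)[0])
    if E_T >= 1.0:
        return -np.inf
    ll = tree.n_tips * np.log(f) - 2 * np.log1p(-E_T)
    ll += float(np.sum(np.log(lam_spec(ages[tree.internal_ids]))))
    ll -= float(np.log(lam_spec(T)))  # root factor removed by conditioning
    nonroot = np.arange(tree.n_nodes) != tree.root
    ll -= float(np.sum(G[tree.parent[nonroot]] - G[nonroot]))
    return float(ll)


# ---------------------------------------------------------------------------
# suite fitting
# ---------------------------------------------------------------------------

def _specs_from_params(model: str, params: dict):
    lam_form, mu_form, _ = BD_MODELS[model]
    lam = RateFunctionSpec("speciation", lam_form, params["lambda0"],
                           params.get("lambda_exp", 0.0))
    mu = RateFunctionSpec("extinction", mu_form, params.get("mu0", 0.0),
                          params.get("mu_exp", 0.0))
    return lam, mu


def _param_layout(model: str):
    lam_form, mu_form, k = BD_MODELS[model]
    names = ["lambda0"]
    if lam_form == "exponential":
        names.append("lambda_exp")
    if mu_form != "zero":
        names.append("mu0")
    if mu_form == "exponential":
        names.append("mu_exp")
    assert len(names) == k
    return names


def _pack(names, params):
    out = []
    for n in names:
        v = params[n]
        out.append(np.log(max(v, 1e-8)) if not n.endswith("_exp") else v)
    return np.array(out)


def _unpack(names, x):
    lo, hi = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])
    d = {}
    for n, v in zip(names, x):
        if n.endswith("_exp"):
            d[n] = float(np.clip(v, -_EXP_BOUND, _EXP_BOUND))
        else:
            d[n] = float(np.exp(np.clip(v, lo, hi)))
    return d


def _fit_one(tree, model, f, x0s):
    names = _param_layout(model)

    def nll(x):
        params = _unpack(names, x)
        lam, mu = _specs_from_params(model, params)
        try:
            ll = bd_loglik(tree, lam, mu, f)
        except (RuntimeError, FloatingPointError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    best, diags = None, []
    for x0 in x0s:
        res = minimize(nll, _pack(names, x0), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7,
                                "maxiter": 400 * len(names)})
        diags.append({"fun": float(res.fun), "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(names, best.x)
    return ModelFit(
        name=model, params=params, loglik=-float(best.fun),
        k=len(names), n=tree.n_tips, converged=bool(best.success),
        diagnostics={"starts": diags, "f": f},
        data_id=data_checksum(tree.lengths),
    )


def fit_bd_model(tree: PhyloTree, model: str, f: float = 1.0,
                 n_starts: int = 3, seed: int = 0) -> ModelFit:
    """ML fit of a single named model from the suite."""
    if model not in BD_MODELS:
        raise ValueError(f"unknown model '{model}'")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    lam0 = max((n / f - 2) / max(tree.total_branch_length / f, 1e-9), 1e-3)
    base = {"lambda0": lam0, "lambda_exp": 0.0, "mu0": lam0 / 5,
            "mu_exp": 0.0}
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append({
            "lambda0": base["lambda0"] * np.exp(rng.normal(0, 0.7)),
            "lambda_exp": rng.normal(0, 0.1),
            "mu0": base["mu0"] * np.exp(rng.normal(0, 0.7)),
            "mu_exp": rng.normal(0, 0.1),
        })
    return _fit_one(tree, model, f, starts)


#: sub-model -> super-models it is nested in (directly)
_NESTING = {
    "yule": ["const_bd", "var_lambda"],
    "const_bd": ["var_lambda_const_mu", "const_lambda_var_mu"],
    "var_lambda": ["var_lambda_const_mu", "var_both"],
    "var_lambda_const_mu": ["var_both"],
    "const_lambda_var_mu": ["var_both"],
}


def fit_bd_suite(tree: PhyloTree, f: float = 1.0, n_starts: int = 3,
                 seed: int = 0, nesting_tol: float = 1e-4) -> dict:
    """Fit all six models; AICc table and best model.

    Nesting violations (a sub-model beating its super-model by more than
    ``nesting_tol``) trigger a restart of the super-model from the
    sub-model's optimum embedded in the larger parameterization.
    """
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    lam0 = max((n / f - 2) / max(tree.total_branch_length / f, 1e-9), 1e-3)
    base = {"lambda0": lam0, "lambda_exp": 0.0, "mu0": lam0 / 5,
            "mu_exp": 0.0}
    fits = {}
    for model in BD_MODELS:
        starts = [base]
        for _ in range(n_starts - 1):
            starts.append({
                "lambda0": base["lambda0"] * np.exp(rng.normal(0, 0.7)),
                "lambda_exp": rng.normal(0, 0.1),
                "mu0": base["mu0"] * np.exp(rng.normal(0, 0.7)),
                "mu_exp": rng.normal(0, 0.1),
            })
        fits[model] = _fit_one(tree, model, f, starts)
    # repair nesting violations
    for _ in range(2):
        fixed = False
        for sub, supers in _NESTING.items():
            for sup in supers:
                if fits[sub].loglik > fits[sup].loglik + nesting_tol:
                    embed = dict(base)
                    embed.update(fits[sub].params)
                    for key in ("lambda_exp", "mu_exp"):
                        embed.setdefault(key, 0.0)
                    if BD_MODELS[sub][1] == "zero":
                        embed["mu0"] = 1e-6
                    refit = _fit_one(tree, sup, f, [embed])
                    if refit.loglik > fits[sup].loglik:
                        fits[sup] = refit
                        fixed = True
        if not fixed:
            break
    table = model_table(list(fits.values()), criterion="aicc")
    return {"fits": fits, "table": table, "best": table[0]["model"]}


def rates_through_time(fit: ModelFit, grid, crown_age: float = None,
                       tree: PhyloTree = None) -> dict:
    """Evaluate lambda(t), mu(t), net rate r(t) and expected richness on
    an age grid (ages in Myr before present, within [0, crown age])."""
    grid = np.asarray(grid, dtype=float)
    lam, mu = _specs_from_params(fit.name, fit.params)
    if tree is not None and crown_age is None:
        crown_age = tree.ages()[tree.root]
    if crown_age is not None and (grid.min() < 0 or grid.max() > crown_age * (1 + 1e-9)):
        raise ValueError("grid outside [0, crown age]")
    lam_t, mu_t = lam(grid), mu(grid)
    out = {"age": grid, "lambda": lam_t, "mu": mu_t, "net": lam_t - mu_t}
    if crown_age is not None:
        out["expected_richness"] = 2 * np.exp(
            _int_rate(lam, grid, crown_age) - _int_rate(mu, grid, crown_age))
    if tree is not None:
        ages = tree.ages()[tree.internal_ids]
        out["ltt"] = np.array([1 + np.sum(ages >= a) for a in grid])
    return out


def _int_rate(spec: RateFunctionSpec, t, T):
    """int_t^T rate(u) du for the supported forms."""
    t = np.asarray(t, dtype=float)
    if spec.form == "zero":
        return np.zeros_like(t)
    if spec.is_constant:
        return spec.rate0 * (T - t)
    a = spec.exponent
    return spec.rate0 / a * (np.exp(a * T) - np.exp(a * t))
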