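"""Discrete-trait rate estimation, stochastic character mapping, and the
BM/OU trait-evolution suite on regime-painted trees.

The pipeline mirrors the standard comparative workflow: estimate a
two-state equal-rates Markov (Mk) transition rate from tip states, draw
stochastic character maps (regime paintings) conditional on the tips,
then fit two Brownian-motion and five Ornstein-Uhlenbeck models per map
(BM1, BMS, OU1, OUM, OUMA, OUMV, OUMVA) and model-average across maps
with AICc weights, checking the Hessian at each optimum.

The OU likelihood is the exact Gaussian one: tip expectations decay
segment-by-segment toward each segment's optimum, covariances accumulate
per-regime OU variance along shared path portions damped by all
subsequent selection, optima are profiled out by generalized least
squares, and alpha = 0 segments take the Brownian limit.  The root is
treated as stationary around the root regime's optimum by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .modelsel import ModelFit, data_checksum
from .tree import PhyloTree, RegimePaintedTree, TreeError

__all__ = ["MkModel", "fit_mk", "mk_loglik", "ancestral_marginals",
           "stochastic_map", "OU_MODELS", "ou_loglik", "fit_ou_model",
           "fit_ou_suite"]

ALPHA_CAP = 50.0  # /Myr; likelihoods at the cap are flagged


# ---------------------------------------------------------------------------
# Mk (equal-rates, two states)
# ---------------------------------------------------------------------------

@dataclass
class MkModel:
    """Equal-rates two-state Markov model: a single rate q (/Myr)."""

    q: float
    root_mode: str = "flat"  # "flat" | "stationary" | "fitzjohn"
    loglik: float = None
    boundary: bool = False
    posterior_draws: np.ndarray = None

    @property
    def posterior_mean(self):
        if self.posterior_draws is None:
            return None
        return float(np.mean(self.posterior_draws))


def _p_matrix(q: float, t: float) -> np.ndarray:
    """Transition probabilities of the symmetric two-state chain."""
    e = np.exp(-2.0 * q * t)
    same = 0.5 * (1 + e)
    diff = 0.5 * (1 - e)
    return np.array([[same, diff], [diff, same]])


def _tip_state_array(tree: PhyloTree, states) -> np.ndarray:
    if hasattr(states, "reindex"):
        states = states.reindex(tree.tip_labels).to_dict()
    out = np.empty(tree.n_tips, dtype=int)
    for k, i in enumerate(tree.tip_ids):
        s = states[tree.labels[i]]
        if s not in (0, 1):
            raise ValueError(f"tip {tree.labels[i]} lacks a binary state")
        out[k] = s
    return out


def _partials(tree: PhyloTree, x: np.ndarray, q: float):
    """Below-partial likelihoods per node with log-rescaling.
    Returns (L, logscale_total)."""
    L = np.zeros((tree.n_nodes, 2))
    for k, i in enumerate(tree.tip_ids):
        L[i, x[k]] = 1.0
    scale = 0.0
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.ones(2)
        for c in kids:
            acc = acc * (_p_matrix(q, tree.lengths[c]) @ L[c])
        s = acc.sum()
        if s <= 0:
            return L, -np.inf
        L[v] = acc / s
        scale += np.log(s)
    return L, scale


def _root_prior(mode: str, L_root: np.ndarray) -> np.ndarray:
    if mode in ("flat", "stationary"):  # identical for equal rates
        return np.array([0.5, 0.5])
    if mode == "fitzjohn":
        s = L_root.sum()
        return L_root / s if s > 0 else np.array([0.5, 0.5])
    raise ValueError(f"unknown root mode '{mode}'")


def mk_loglik(tree: PhyloTree, states, q: float,
              root_mode: str = "flat") -> float:
    x = _tip_state_array(tree, states)
    L, scale = _partials(tree, x, q)
    pi = _root_prior(root_mode, L[tree.root])
    lik = float(pi @ L[tree.root])
    return np.log(lik) + scale if lik > 0 else -np.inf


def fit_mk(tree: PhyloTree, states, method: str = "ML",
           root_mode: str = "flat", seed: int = 0,
           mcmc_iter: int = 1000, mcmc_thin: int = 10) -> MkModel:
    """Estimate the single Mk rate by ML, optionally followed by an MCMC
    sample under an exponential prior with mean set to the ML estimate.

    Monomorphic tip states drive q to the lower boundary; this is
    flagged, not an error.
    """
    x = _tip_state_array(tree, states)
    mono = len(set(x.tolist())) == 1

    def nll(logq):
        return -mk_loglik(tree, states, float(np.exp(logq)), root_mode)

    res = minimize_scalar(nll, bounds=(np.log(1e-8), np.log(1e3)),
                          method="bounded", options={"xatol": 1e-8})
    q_hat = float(np.exp(res.x))
    boundary = mono or q_hat <= 1.5e-8
    model = MkModel(q=q_hat, root_mode=root_mode, loglik=-float(res.fun),
                    boundary=boundary)
    if method.upper() == "MCMC":
        rng = np.random.default_rng(seed)
        prior_mean = max(q_hat, 1e-6)
        q = prior_mean
        ll = mk_loglik(tree, states, q, root_mode) - q / prior_mean
        draws = []
        for it in range(mcmc_iter):
            prop = q * np.exp(rng.normal(0, 0.3))
            lp = mk_loglik(tree, states, prop, root_mode) - prop / prior_mean
            # lognormal proposal needs the Jacobian q'/q
            if np.log(rng.random()) < lp - ll + np.log(prop / q):
                q, ll = prop, lp
            if it % mcmc_thin == 0:
                draws.append(q)
        model.posterior_draws = np.array(draws)
        model.q = model.posterior_mean
    elif method.upper() != "ML":
        raise ValueError("method must be 'ML' or 'MCMC'")
    return model


def ancestral_marginals(tree: PhyloTree, states, mk: MkModel) -> np.ndarray:
    """Marginal ancestral state probabilities (n_nodes, 2) by the
    standard two-pass (below x above) message algorithm."""
    x = _tip_state_array(tree, states)
    q = mk.q
    L, _ = _partials(tree, x, q)
    A = np.zeros((tree.n_nodes, 2))
    A[tree.root] = _root_prior(mk.root_mode if mk.root_mode != "fitzjohn"
                               else "flat", L[tree.root])
    for v in tree.preorder():
        kids = tree.children[v]
        below = {c: _p_matrix(q, tree.lengths[c]) @ L[c] for c in kids}
        for c in kids:
            msg = A[v].copy()
            for b in kids:
                if b != c:
                    msg = msg * below[b]
            A[c] = _p_matrix(q, tree.lengths[c]).T @ msg
            s = A[c].sum()
            if s > 0:
                A[c] /= s
    marg = A * L
    marg /= marg.sum(axis=1, keepdims=True)
    return marg


def _sample_bridge_flips(rng, lam: float, same: bool) -> int:
    """Number of state flips on a symmetric two-state bridge, by
    uniformization at rate q (every virtual jump is a real flip for the
    symmetric chain), so N is parity-restricted Poisson(lam = q t)."""
    if lam == 0:
        if not same:
            raise RuntimeError("endpoint change with zero rate")
        return 0
    if same:
        n, term, norm = 0, 1.0, np.cosh(lam)
    else:
        n, term, norm = 1, lam, np.sinh(lam)
    u = rng.random() * norm * np.exp(-lam)
    term *= np.exp(-lam)
    while u > term and n < 10_000:
        u -= term
        n += 2
        term *= lam * lam / ((n - 1) * n)
    return n


def stochastic_map(tree: PhyloTree, states, mk: MkModel, n_maps: int = 100,
                   seed: int = 0) -> list:
    """Stochastic character maps: sample node states from their joint
    conditional distribution, then each branch path conditional on its
    endpoints.  Every map's tip regimes equal the observed tip states."""
    x = _tip_state_array(tree, states)
    q = mk.q
    L, _ = _partials(tree, x, q)
    rng = np.random.default_rng(seed)
    pre = [int(v) for v in tree.preorder() if v != tree.root]
    parent = tree.parent
    lengths = tree.lengths
    # per-branch: P(s_child | s_parent) * L_child, normalized per parent row
    cond = np.empty((tree.n_nodes, 2, 2))
    for v in pre:
        w = _p_matrix(q, lengths[v]) * L[v][None, :]
        tot = w.sum(axis=1, keepdims=True)
        # rows with zero mass belong to parent states that can never be
        # sampled; keep them finite
        cond[v] = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 0.0)
    pi = _root_prior(mk.root_mode, L[tree.root])
    pr = pi * L[tree.root]
    pr = pr / pr.sum()
    maps = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=np.int64)
        node_state[tree.root] = 1 if rng.random() < pr[1] else 0
        paintings = [None] * tree.n_nodes
        for v in pre:
            sp = node_state[parent[v]]
            sc = 1 if rng.random() < cond[v, sp, 1] else 0
            node_state[v] = sc
            t = lengths[v]
            nflips = _sample_bridge_flips(rng, q * t, same=(sp == sc))
            if nflips == 0:
                paintings[v] = [(int(sp), float(t))]
            else:
                times = np.sort(rng.uniform(0, t, size=nflips))
                bounds = np.concatenate(([0.0], times, [t]))
                s = sp
                segs = []
                for k in range(nflips + 1):
                    segs.append((int(s), float(bounds[k + 1] - bounds[k])))
                    s = 1 - s
                paintings[v] = segs
        maps.append(RegimePaintedTree(tree, paintings, regimes=(0, 1)))
    return maps


# ---------------------------------------------------------------------------
# BM / OU suite on painted trees
# ---------------------------------------------------------------------------

#: model -> (per-regime alpha, per-regime sigma2, per-regime theta)
OU_MODELS = {
    "BM1": (False, False, False),
    "BMS": (False, True, False),
    "OU1": (False, False, False),
    "OUM": (False, False, True),
    "OUMA": (True, False, True),
    "OUMV": (False, True, True),
    "OUMVA": (True, True, True),
}
_BM_MODELS = ("BM1", "BMS")


def _as_regime_dict(value, regimes):
    if isinstance(value, dict):
        return {r: float(value[r]) for r in regimes}
    return {r: float(value) for r in regimes}


def _tip_trait(tree: PhyloTree, trait) -> np.ndarray:
    if hasattr(trait, "reindex"):
        return trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    if isinstance(trait, dict):
        return np.array([trait[l] for l in tree.tip_labels], dtype=float)
    return np.asarray(trait, dtype=float)


def _moments(painted: RegimePaintedTree, alpha: dict, sigma2: dict,
             model: str, root_mode: str):
    """Per-node damping A, variance Var, and theta design rows C.

    Returns (A, Var, C, design_names): C[v] holds the coefficients of the
    node's expectation on the design parameters (per-regime optima for
    multi-optimum OU models, a single optimum for OU1, the root state
    for BM models; plus a damped root column under root_mode='fixed')."""
    tree = painted.tree
    regimes = list(painted.regimes)
    is_bm = model in _BM_MODELS
    if is_bm:
        design = ["root_state"]
    elif OU_MODELS[model][2]:
        design = [f"theta[{r}]" for r in regimes]
    else:
        design = ["theta"]
    extra_root = (not is_bm) and root_mode == "fixed"
    if extra_root:
        design = design + ["root_state"]
    p = len(design)
    ridx = {r: i for i, r in enumerate(regimes)}

    A = np.ones(tree.n_nodes)
    Var = np.zeros(tree.n_nodes)
    C = np.zeros((tree.n_nodes, p))
    root_regime = painted.root_regime()
    if is_bm:
        C[tree.root, 0] = 1.0
    elif extra_root:
        C[tree.root, -1] = 1.0
    elif OU_MODELS[model][2]:
        C[tree.root, ridx[root_regime]] = 1.0
    else:
        C[tree.root, 0] = 1.0
    if not is_bm and root_mode == "stationary":
        a0, s0 = alpha[root_regime], sigma2[root_regime]
        Var[tree.root] = s0 / (2 * a0) if a0 > 0 else 0.0

    for v in tree.preorder():
        if v == tree.root:
            continue
        par = tree.parent[v]
        a_e, v_e = 1.0, 0.0
        c_e = np.zeros(p)
        for r, d in painted.paintings[v]:
            ar, s2r = (0.0, sigma2[r]) if is_bm else (alpha[r], sigma2[r])
            if ar > 0:
                e = np.exp(-ar * d)
                one_m_e = -np.expm1(-ar * d)  # 1 - e, cancellation-safe
                v_seg = s2r * (-np.expm1(-2 * ar * d)) / (2 * ar)
            else:
                e, one_m_e = 1.0, 0.0
                v_seg = s2r * d
            a_e *= e
            v_e = v_e * e * e + v_seg
            c_e *= e
            if not is_bm:
                j = ridx[r] if OU_MODELS[model][2] else 0
                c_e[j] += one_m_e
        A[v] = A[par] * a_e
        Var[v] = Var[par] * a_e * a_e + v_e
        C[v] = a_e * C[par] + c_e
    return A, Var, C, design


def ou_loglik(painted: RegimePaintedTree, trait, model: str,
              alpha=None, sigma2=None, root_mode: str = "stationary"):
    """Gaussian log-likelihood of a continuous trait under the given
    BM/OU model on a painted tree, with the optima profiled out by GLS.

    Returns (loglik, theta_hat) where theta_hat maps design names to the
    GLS estimates.  ``alpha``/``sigma2`` are scalars or regime dicts as
    the model requires (alpha ignored for BM models).
    """
    tree = painted.tree
    if tree.n_tips < 4:
        raise ValueError("OU likelihood needs at least 4 tips")
    if model not in OU_MODELS:
        raise ValueError(f"unknown model '{model}'")
    regimes = list(painted.regimes)
    sigma2 = _as_regime_dict(sigma2, regimes)
    alpha = (_as_regime_dict(0.0, regimes) if model in _BM_MODELS
             else _as_regime_dict(alpha, regimes))
    for r in regimes:
        if sigma2[r] <= 0 or alpha[r] < 0:
            raise ValueError("need sigma2 > 0 and alpha >= 0")
    x = _tip_trait(tree, trait)

    A, Var, C, design = _moments(painted, alpha, sigma2, model, root_mode)
    tips = tree.tip_ids
    M = tree.mrca_matrix()
    At = A[tips]
    Am = A[M]
    with np.errstate(divide="ignore", invalid="ignore"):
        V = Var[M] * np.where(Am > 0, (At[:, None] / Am) * (At[None, :] / Am), 0.0)
    np.fill_diagonal(V, Var[tips])
    W = C[tips]

    n = x.size
    try:
        cf = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, {}
    solve = lambda b: np.linalg.solve(cf.T, np.linalg.solve(cf, b))
    # whitened least squares; the min-norm solution keeps the profiled
    # optima finite when a regime's design column nearly vanishes
    # (alpha -> 0 ridge) - such fits are flagged by the fitter
    Aw = np.linalg.solve(cf, W)
    bw = np.linalg.solve(cf, x)
    theta = np.linalg.lstsq(Aw, bw, rcond=1e-10)[0]
    r = x - W @ theta
    quad = r @ solve(r)
    logdet = 2 * np.sum(np.log(np.diag(cf)))
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    if not np.isfinite(ll):
        return -np.inf, {}
    return float(ll), dict(zip(design, theta))


def _ou_param_layout(model: str, regimes):
    var_a, var_s, _ = OU_MODELS[model]
    names = []
    if model not in _BM_MODELS:
        names += ([f"alpha[{r}]" for r in regimes] if var_a else ["alpha"])
    names += ([f"sigma2[{r}]" for r in regimes] if var_s else ["sigma2"])
    return names


def _expand_ou(names, x, regimes):
    vals = dict(zip(names, np.exp(x)))
    if any(k.startswith("alpha[") for k in vals):
        alpha = {r: min(vals[f"alpha[{r}]"], ALPHA_CAP) for r in regimes}
    elif "alpha" in vals:
        alpha = min(vals["alpha"], ALPHA_CAP)
    else:
        alpha = 0.0
    if any(k.startswith("sigma2[") for k in vals):
        sigma2 = {r: vals[f"sigma2[{r}]"] for r in regimes}
    else:
        sigma2 = vals["sigma2"]
    return alpha, sigma2


def fit_ou_model(painted: RegimePaintedTree, trait, model: str,
                 root_mode: str = "stationary", n_starts: int = 2,
                 seed: int = 0, compute_hessian: bool = True,
                 extra_starts=()) -> ModelFit:
    """ML fit of one BM/OU model on one painting (multi-start, log-scale
    optimization; parameter count includes the GLS-profiled optima).
    ``extra_starts``: extra (alpha, sigma2) starting values, scalars or
    regime dicts - e.g. a nested sub-model's optimum."""
    tree = painted.tree
    regimes = list(painted.regimes)
    x = _tip_trait(tree, trait)
    names = _ou_param_layout(model, regimes)
    rng = np.random.default_rng(seed)

    height = tree.height
    s2_0 = max(np.var(x) / max(height, 1e-9), 1e-8)
    a_0 = np.log(2) / max(height / 2, 1e-9)
    base = []
    for nm in names:
        base.append(np.log(a_0) if nm.startswith("alpha") else np.log(s2_0))
    base = np.array(base)

    def nll(z):
        alpha, sigma2 = _expand_ou(names, z, regimes)
        try:
            ll, _ = ou_loglik(painted, x, model, alpha, sigma2, root_mode)
        except (ValueError, FloatingPointError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    by_str = {str(r): r for r in regimes}

    def _pick(value, key):
        if not isinstance(value, dict):
            return value
        if key is None:
            return float(np.mean(list(value.values())))
        return value[by_str[key]]

    def _z_from(alpha_v, sigma2_v):
        z = []
        for nm in names:
            if nm.startswith("alpha"):
                key = nm[6:-1] if nm.startswith("alpha[") else None
                z.append(_pick(alpha_v, key))
            else:
                key = nm[7:-1] if nm.startswith("sigma2[") else None
                z.append(_pick(sigma2_v, key))
        return np.log(np.maximum(np.asarray(z, dtype=float), 1e-8))

    start_points = [base]
    start_points += [base + rng.normal(0, 0.8, size=len(names))
                     for _ in range(n_starts - 1)]
    start_points += [_z_from(a, s) for a, s in extra_starts]

    best, diags = None, []
    for z0 in start_points:
        res = minimize(nll, z0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7,
                                "maxiter": 500 * max(len(names), 1)})
        diags.append({"fun": float(res.fun), "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    alpha, sigma2 = _expand_ou(names, best.x, regimes)
    ll, theta = ou_loglik(painted, x, model, alpha, sigma2, root_mode)
    theta_identifiable = _theta_identifiable(painted, x, model, alpha,
                                             sigma2, root_mode)
    params = {}
    if model not in _BM_MODELS:
        params["alpha"] = alpha
    params["sigma2"] = sigma2
    params.update(theta)
    k = len(names) + len(theta)
    heig = None
    if compute_hessian and len(names) > 0:
        heig = _fd_hess_eig(nll, best.x)
    at_cap = (isinstance(alpha, dict) and any(
        abs(a - ALPHA_CAP) < 1e-9 for a in alpha.values())) or (
        isinstance(alpha, float) and abs(alpha - ALPHA_CAP) < 1e-9)
    return ModelFit(
        name=model, params=params, loglik=float(ll), k=k, n=tree.n_tips,
        converged=bool(best.success) and best.fun < 1e9,
        hessian_eigenvalues=heig,
        diagnostics={"starts": diags, "alpha_at_cap": at_cap,
                     "root_mode": root_mode,
                     "theta_identifiable": theta_identifiable},
        data_id=data_checksum(tree.lengths, x),
    )


def _theta_identifiable(painted, x, model, alpha, sigma2, root_mode,
                        rcond: float = 1e-6, se_factor: float = 10.0) -> bool:
    """False when some optimum barely enters the tip expectations
    (near-zero whitened design direction) or its GLS standard error
    exceeds ``se_factor`` times the trait range - the alpha -> 0 ridge,
    where the fitted optimum is statistically meaningless."""
    regimes = list(painted.regimes)
    s2 = _as_regime_dict(sigma2, regimes)
    al = (_as_regime_dict(0.0, regimes) if model in _BM_MODELS
          else _as_regime_dict(alpha, regimes))
    A, Var, C, _ = _moments(painted, al, s2, model, root_mode)
    tree = painted.tree
    tips = tree.tip_ids
    M = tree.mrca_matrix()
    At = A[tips]
    Am = A[M]
    with np.errstate(divide="ignore", invalid="ignore"):
        V = Var[M] * np.where(Am > 0, (At[:, None] / Am) * (At[None, :] / Am),
                              0.0)
    np.fill_diagonal(V, Var[tips])
    try:
        cf = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return False
    Aw = np.linalg.solve(cf, C[tips])
    s = np.linalg.svd(Aw, compute_uv=False)
    if not s.min() > rcond * max(s.max(), 1e-300):
        return False
    xv = _tip_trait(tree, x)
    scale = max(np.ptp(xv), 1e-12)
    cov = np.linalg.inv(Aw.T @ Aw)
    return bool(np.sqrt(np.diag(cov)).max() <= se_factor * scale)


def _fd_hess_eig(fun, z, h: float = 1e-3):
    k = z.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(z + ei + ej) - fun(z + ei - ej)
                - fun(z - ei + ej) + fun(z - ei - ej)) / (4 * h * h)
    return np.linalg.eigvalsh(H)


def fit_ou_suite(maps, trait, models=None, root_mode: str = "stationary",
                 n_starts: int = 2, seed: int = 0,
                 compute_hessian: bool = True) -> dict:
    """Fit the model suite on every painting and model-average.

    Returns per-map AICc tables and a cross-map summary: mean AICc weight
    per model, and parameter mean +/- SD across maps under the best model
    (fits with non-positive Hessian eigenvalues are flagged and excluded
    from the averages).
    """
    if models is None:
        models = list(OU_MODELS)
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one painting")
    tipsets = {tuple(m.tree.tip_labels) for m in maps}
    if len(tipsets) > 1:
        raise ValueError("all maps must share the same tip set")
    rng = np.random.default_rng(seed)
    per_map = []
    weights = {m: [] for m in models}
    fits_by_model = {m: [] for m in models}
    for painted in maps:
        fits = []
        for model in models:
            fit = fit_ou_model(painted, trait, model, root_mode=root_mode,
                               n_starts=n_starts,
                               seed=int(rng.integers(2 ** 31)),
                               compute_hessian=compute_hessian)
            fits.append(fit)
            fits_by_model[model].append(fit)
        aiccs = np.array([f.aicc for f in fits])
        d = aiccs - aiccs.min()
        w = np.exp(-0.5 * d)
        w /= w.sum()
        for model, wi in zip(models, w):
            weights[model].append(float(wi))
        per_map.append({"fits": {f.name: f for f in fits},
                        "weights": dict(zip(models, w.tolist()))})
    mean_w = {m: float(np.mean(weights[m])) for m in models}
    best = max(mean_w, key=mean_w.get)
    ranked = sorted(mean_w.items(), key=lambda kv: -kv[1])
    summary = {
        "mean_weights": mean_w,
        "best": best,
        "runner_up": ranked[1][0] if len(ranked) > 1 else None,
        "delta_mean_weight": (ranked[0][1] - ranked[1][1]
                              if len(ranked) > 1 else None),
        "params": _summarize_params(fits_by_model[best]),
        "n_maps": len(maps),
    }
    return {"per_map": per_map, "summary": summary}


def _flatten_params(fit: ModelFit) -> dict:
    flat = {}
    for key, val in fit.params.items():
        if isinstance(val, dict):
            for r, v in val.items():
                flat[f"{key}[{r}]"] = v
        else:
            flat[key] = val
    return flat


def _summarize_params(fits) -> dict:
    ok = [f for f in fits
          if f.hessian_positive in (True, None) and f.converged
          and f.diagnostics.get("theta_identifiable", True)]
    out = {"n_used": len(ok), "n_flagged": len(fits) - len(ok)}
    if not ok:
        return out
    keys = _flatten_params(ok[0]).keys()
    table = {k: [] for k in keys}
    for f in ok:
        for k, v in _flatten_params(f).items():
            table[k].append(v)
    out["mean"] = {k: float(np.mean(v)) for k, v in table.items()}
    out["sd"] = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                 for k, v in table.items()}
    return out
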