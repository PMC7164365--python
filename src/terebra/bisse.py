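"""Binary State Speciation and Extinction (BiSSE) likelihood and fits.

The model gives each lineage a binary character that sets its speciation
and extinction rates (lambda_i, mu_i) and flips at rates q01/q10.  Along
each branch the standard coupled ODEs are integrated tipward-to-rootward:

    dE_i/dt = mu_i - (lambda_i + mu_i + q_ij) E_i + lambda_i E_i^2 + q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + q_ij) D_i + q_ij D_j + 2 lambda_i E_i D_i

with tip conditions E_i(0) = 1 - f_i and D_i(0) = f_i for the observed
state (state-specific sampling fractions f_i), D multiplied across
daughters and by lambda_i at nodes, FitzJohn relative-D weighting at the
root, and conditioning on survival of both crown lineages.

Because the tree is ultrametric and the E system does not depend on the
branch, E is solved once as a function of age; D is then a linear
2-component ODE shared by all branches, advanced for every active branch
simultaneously between successive node ages (fixed-substep RK4 on the
dense E interpolant), with per-branch log-rescaling against underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .modelsel import ModelFit, data_checksum
from .simulate import BisseParams
from .tree import PhyloTree, TreeError

__all__ = ["BisseParams", "bisse_loglik", "fit_bisse", "bisse_model_lattice",
           "yule_loglik"]

_PARAM_NAMES = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")
_RATE_BOUNDS = (1e-8, 1e3)


def yule_loglik(tree: PhyloTree, lam: float) -> float:
    """Closed-form pure-birth likelihood of an ultrametric tree,
    conditioned on crown survival: (n-2) log lambda - lambda * total
    branch length."""
    n = tree.n_tips
    return (n - 2) * np.log(lam) - lam * tree.total_branch_length


def _check_inputs(tree: PhyloTree, states, f):
    if not tree.is_binary():
        raise TreeError("BiSSE requires a fully binary tree")
    if not tree.is_ultrametric():
        raise TreeError("BiSSE requires an ultrametric tree")
    f0, f1 = f
    if not (0 < f0 <= 1 and 0 < f1 <= 1):
        raise ValueError("sampling fractions must lie in (0, 1]")
    labels = tree.tip_labels
    if hasattr(states, "reindex"):
        states = states.reindex(labels).to_dict()
    missing = [l for l in labels if l not in states or states[l] not in (0, 1)]
    if missing:
        raise ValueError(f"tips without a valid binary state: {missing}")
    return {l: int(states[l]) for l in labels}


def _integrate_E_impl(dts, e0, e1, lam0, lam1, mu0, mu1, q01, q10):
    """RK4 integration of the (autonomous) E system over consecutive
    half-steps; returns E at every half-grid point (n+1, 2)."""
    n = dts.size
    out = np.empty((n + 1, 2))
    out[0, 0] = e0
    out[0, 1] = e1
    for k in range(n):
        h = dts[k]
        x0 = out[k, 0]; x1 = out[k, 1]

        k10 = mu0 - (lam0 + mu0 + q01) * x0 + lam0 * x0 * x0 + q01 * x1
        k11 = mu1 - (lam1 + mu1 + q10) * x1 + lam1 * x1 * x1 + q10 * x0
        y0 = x0 + 0.5 * h * k10; y1 = x1 + 0.5 * h * k11
        k20 = mu0 - (lam0 + mu0 + q01) * y0 + lam0 * y0 * y0 + q01 * y1
        k21 = mu1 - (lam1 + mu1 + q10) * y1 + lam1 * y1 * y1 + q10 * y0
        y0 = x0 + 0.5 * h * k20; y1 = x1 + 0.5 * h * k21
        k30 = mu0 - (lam0 + mu0 + q01) * y0 + lam0 * y0 * y0 + q01 * y1
        k31 = mu1 - (lam1 + mu1 + q10) * y1 + lam1 * y1 * y1 + q10 * y0
        y0 = x0 + h * k30; y1 = x1 + h * k31
        k40 = mu0 - (lam0 + mu0 + q01) * y0 + lam0 * y0 * y0 + q01 * y1
        k41 = mu1 - (lam1 + mu1 + q10) * y1 + lam1 * y1 * y1 + q10 * y0
        out[k + 1, 0] = x0 + h / 6.0 * (k10 + 2 * k20 + 2 * k30 + k40)
        out[k + 1, 1] = x1 + h / 6.0 * (k11 + 2 * k21 + 2 * k31 + k41)
    return out


def _sweep_impl(D, ls, tips, nodes, cl, cr, offsets, hs,
                d0a, d1a, d0b, d1b, d0c, d1c,
                q01, q10, lam0, lam1, root):
    """Advance all active branches through the fixed RK4 schedule,
    merging daughters at each node age; returns False on underflow."""
    n_active = tips.size
    active = np.empty(D.shape[0], dtype=np.int64)
    active[:n_active] = tips
    for j in range(nodes.size):
        for s in range(offsets[j], offsets[j + 1]):
            h = hs[s]
            a0 = d0a[s]; a1 = d1a[s]
            b0 = d0b[s]; b1 = d1b[s]
            c0 = d0c[s]; c1 = d1c[s]
            for ii in range(n_active):
                i = active[ii]
                x0 = D[i, 0]; x1 = D[i, 1]
                k10 = a0 * x0 + q01 * x1; k11 = q10 * x0 + a1 * x1
                y0 = x0 + 0.5 * h * k10; y1 = x1 + 0.5 * h * k11
                k20 = b0 * y0 + q01 * y1; k21 = q10 * y0 + b1 * y1
                y0 = x0 + 0.5 * h * k20; y1 = x1 + 0.5 * h * k21
                k30 = b0 * y0 + q01 * y1; k31 = q10 * y0 + b1 * y1
                y0 = x0 + h * k30; y1 = x1 + h * k31
                k40 = c0 * y0 + q01 * y1; k41 = q10 * y0 + c1 * y1
                D[i, 0] = x0 + h / 6.0 * (k10 + 2 * k20 + 2 * k30 + k40)
                D[i, 1] = x1 + h / 6.0 * (k11 + 2 * k21 + 2 * k31 + k41)
        if offsets[j + 1] > offsets[j]:
            for ii in range(n_active):
                i = active[ii]
                tot = D[i, 0] + D[i, 1]
                if not (tot > 0) or not np.isfinite(tot):
                    return False
                D[i, 0] /= tot; D[i, 1] /= tot
                ls[i] += np.log(tot)
        v = nodes[j]; left = cl[j]; right = cr[j]
        D[v, 0] = D[left, 0] * D[right, 0] * lam0
        D[v, 1] = D[left, 1] * D[right, 1] * lam1
        ls[v] = ls[left] + ls[right]
        sv = D[v, 0] + D[v, 1]
        if not (sv > 0) or not np.isfinite(sv):
            return False
        D[v, 0] /= sv; D[v, 1] /= sv
        ls[v] += np.log(sv)
        w = 0
        for ii in range(n_active):
            if active[ii] != left and active[ii] != right:
                active[w] = active[ii]
                w += 1
        active[w] = v
        n_active = w + 1
    return True


try:  # the JIT is a speed-up only; the pure-Python path is identical
    from numba import njit as _njit

    _sweep = _njit(cache=True)(_sweep_impl)
    _integrate_E = _njit(cache=True)(_integrate_E_impl)
except ImportError:  # pragma: no cover
    _sweep = _sweep_impl
    _integrate_E = _integrate_E_impl


def _schedule(tree: PhyloTree, hmax: float):
    """Fixed RK4 step schedule between successive node ages, cached on
    the tree (depends only on topology, ages and the step bound)."""
    cache = getattr(tree, "_bisse_schedules", None)
    if cache is None:
        cache = tree._bisse_schedules = {}
    if hmax in cache:
        return cache[hmax]
    ages = np.where(tree.ages() < 0, 0.0, tree.ages())
    internal = sorted((int(v) for v in tree.internal_ids),
                      key=lambda v: ages[v])
    ev = np.concatenate(([0.0], [ages[v] for v in internal]))
    counts, hs = [], []
    for j in range(len(internal)):
        span = ev[j + 1] - ev[j]
        if span <= 0:
            counts.append(0)
            continue
        nsub = max(1, int(np.ceil(span / hmax)))
        counts.append(nsub)
        hs.extend([span / nsub] * nsub)
    hs = np.asarray(hs)
    offsets = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    half_dts = np.repeat(hs, 2) * 0.5
    sched = {
        "internal": internal,
        "ages": ages,
        "hs": hs,
        "offsets": offsets,
        "half_dts": half_dts,
        "node_ids": np.array(internal, dtype=np.int64),
        "children_left": np.array(
            [tree.children[v][0] for v in internal], dtype=np.int64),
        "children_right": np.array(
            [tree.children[v][1] for v in internal], dtype=np.int64),
        "tips": np.asarray(tree.tip_ids, dtype=np.int64),
    }
    if len(cache) > 32:
        cache.clear()
    cache[hmax] = sched
    return sched


def bisse_loglik(tree: PhyloTree, states, params: BisseParams,
                 f=(1.0, 1.0), root_mode="fitzjohn",
                 condition_surv: bool = True,
                 max_step_fraction: float = 1e-3) -> float:
    """Log-likelihood of tip states and tree under BiSSE.

    ``root_mode``: "fitzjohn" (relative-D weights), "flat", or a length-2
    probability vector.  ``max_step_fraction`` bounds the RK4 substep as
    a fraction of the root age.
    """
    states = _check_inputs(tree, states, f)
    root_age = float(np.max(tree.ages()))
    # the RK4 step must resolve the fastest total event rate (stability
    # limit); quantize to powers of two so schedules cache well
    rate_tot = max(params.lambda0 + params.mu0 + params.q01,
                   params.lambda1 + params.mu1 + params.q10, 1e-12)
    h_desired = min(root_age * max_step_fraction, 0.4 / rate_tot)
    n_steps = 2 ** int(np.ceil(np.log2(max(root_age / h_desired, 1.0))))
    hmax = root_age / n_steps
    sched = _schedule(tree, hmax)

    # E depends only on age, not on the branch: integrate it once on the
    # half-step grid shared with the D sweep
    E = _integrate_E(sched["half_dts"], 1.0 - f[0], 1.0 - f[1],
                     params.lambda0, params.lambda1, params.mu0, params.mu1,
                     params.q01, params.q10)
    E_a, E_b, E_c = E[0:-1:2], E[1::2], E[2::2]
    lam_vec = np.array([params.lambda0, params.lambda1])
    mu_vec = np.array([params.mu0, params.mu1])
    q_vec = np.array([params.q01, params.q10])
    base = -(lam_vec + mu_vec + q_vec)
    da = base[None, :] + 2 * lam_vec[None, :] * E_a
    db = base[None, :] + 2 * lam_vec[None, :] * E_b
    dc = base[None, :] + 2 * lam_vec[None, :] * E_c

    # D value and log-scale at the *bottom* (tipward end) of each branch,
    # filled in as nodes resolve; advanced to each next event age.
    D = np.zeros((tree.n_nodes, 2))
    ls = np.zeros(tree.n_nodes)
    for i in sched["tips"]:
        s = states[tree.labels[i]]
        D[i, s] = f[s]

    ok = _sweep(D, ls, sched["tips"], sched["node_ids"],
                sched["children_left"], sched["children_right"],
                sched["offsets"], sched["hs"],
                np.ascontiguousarray(da[:, 0]), np.ascontiguousarray(da[:, 1]),
                np.ascontiguousarray(db[:, 0]), np.ascontiguousarray(db[:, 1]),
                np.ascontiguousarray(dc[:, 0]), np.ascontiguousarray(dc[:, 1]),
                params.q01, params.q10,
                params.lambda0, params.lambda1, tree.root)
    if not ok:
        return -np.inf

    d_root = D[tree.root]
    E_root = E[-1]
    if isinstance(root_mode, str) and root_mode == "fitzjohn":
        w = d_root / d_root.sum()
    elif isinstance(root_mode, str) and root_mode == "flat":
        w = np.array([0.5, 0.5])
    else:
        w = np.asarray(root_mode, dtype=float)
    lik = float(w @ d_root)
    ll = np.log(lik) + ls[tree.root]
    if condition_surv:
        cond = float(w @ (lam_vec * (1 - E_root) ** 2))
        if cond <= 0:
            return -np.inf
        ll -= np.log(cond)
    return float(ll)


# ---------------------------------------------------------------------------
# constrained ML fitting
# ---------------------------------------------------------------------------

def _resolve_constraint(constraint: dict):
    """Constraint entries map parameter name -> another name (equality)
    or a number (fixed).  Returns (free_names, expander)."""
    constraint = dict(constraint or {})
    for k, v in constraint.items():
        if k not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter '{k}'")
        if isinstance(v, str) and v not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter '{v}'")
        if isinstance(v, str) and v in constraint:
            raise ValueError("chained constraints are not supported")
    free = [p for p in _PARAM_NAMES if p not in constraint]

    def expand(values):
        d = dict(zip(free, values))
        for k, v in constraint.items():
            d[k] = d[v] if isinstance(v, str) else float(v)
        return BisseParams(**d)

    return free, expand


def bisse_model_lattice():
    """The shipped constrained-scenario lattice.

    Spans the study's reported fits: the full six-parameter model, single
    equalities, the three-parameter state-independent null, and
    irreversible (q10 = 0) variants.
    """
    eq_l = {"lambda1": "lambda0"}
    eq_m = {"mu1": "mu0"}
    eq_q = {"q10": "q01"}
    irrev = {"q10": 0.0}
    return {
        "full": {},
        "equal.lambda": {**eq_l},
        "equal.mu": {**eq_m},
        "equal.q": {**eq_q},
        "equal.lambda.mu": {**eq_l, **eq_m},
        "equal.all": {**eq_l, **eq_m, **eq_q},
        "full.irrev": {**irrev},
        "equal.lambda.irrev": {**eq_l, **irrev},
        "equal.mu.irrev": {**eq_m, **irrev},
        "equal.lambda.mu.irrev": {**eq_l, **eq_m, **irrev},
    }


def _heuristic_start(tree: PhyloTree, f) -> dict:
    """Tree-wide pure-birth rate as a speciation guess, corrected for
    sampling; modest extinction and transition rates."""
    fbar = 0.5 * (f[0] + f[1])
    n_eff = tree.n_tips / fbar
    lam = max((n_eff - 2) / max(tree.total_branch_length / fbar, 1e-6), 1e-3)
    return {"lambda0": lam, "lambda1": lam, "mu0": lam / 4, "mu1": lam / 4,
            "q01": lam / 5, "q10": lam / 5}


def fit_bisse(tree: PhyloTree, states, constraint=None, f=(1.0, 1.0),
              n_starts: int = 5, seed: int = 0, name: str = None,
              compute_hessian: bool = False, extra_starts=(),
              **loglik_kwargs) -> ModelFit:
    """ML fit of a (constrained) BiSSE model, log-parameterized and
    multi-started (one heuristic start plus perturbed replicates;
    ``extra_starts`` accepts parameter dicts, e.g. a nested sub-model's
    optimum, as additional starting points)."""
    states_map = _check_inputs(tree, states, f)
    free, expand = _resolve_constraint(constraint)
    k = len(free)
    rng = np.random.default_rng(seed)
    start = _heuristic_start(tree, f)
    lo, hi = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])

    def nll(logx):
        x = np.exp(np.clip(logx, lo, hi))
        try:
            ll = bisse_loglik(tree, states_map, expand(x), f, **loglik_kwargs)
        except (RuntimeError, FloatingPointError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    best = None
    diagnostics = []
    x0 = np.log([max(start[p], 1e-6) for p in free])
    start_points = [x0]
    start_points += [x0 + rng.normal(0, 0.75, size=k)
                     for _ in range(n_starts - 1)]
    for extra in extra_starts:
        start_points.append(np.log([max(extra[p], 1e-6) for p in free]))
    for s, xs in enumerate(start_points):
        res = minimize(nll, xs, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6,
                                "maxiter": 400 * k})
        diagnostics.append({"start": s, "fun": float(res.fun),
                            "converged": bool(res.success),
                            "nfev": int(res.nfev)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError(f"all BiSSE starts failed: {diagnostics}")
    est = expand(np.exp(np.clip(best.x, lo, hi)))
    heig = None
    if compute_hessian:
        heig = _fd_hessian_eigvals(nll, best.x)
    return ModelFit(
        name=name or ("full" if not constraint else str(constraint)),
        params={p: getattr(est, p) for p in _PARAM_NAMES},
        loglik=-float(best.fun), k=k, n=tree.n_tips,
        converged=bool(best.success),
        hessian_eigenvalues=heig,
        diagnostics={"starts": diagnostics, "free": free,
                     "sampling_fractions": tuple(f)},
        data_id=data_checksum(
            tree.lengths, np.array([states_map[l] for l in tree.tip_labels])),
    )


def _fd_hessian_eigvals(fun, x, h: float = 1e-4):
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return np.linalg.eigvalsh(H)
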