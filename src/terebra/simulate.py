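"""Seed-deterministic simulators for every downstream analysis stage.

The generators emulate the statistical structure the analyses assume:
birth-death trees with incomplete extant sampling, binary traits
co-evolving with diversification (the two-state speciation-extinction
process), Mk binary traits on a fixed tree, BM/OU continuous traits on
regime-painted trees, multi-station occurrence records, and abundance
samples with singletons and doubletons.

Trees are simulated forward in time with a thinning (rejection) scheme
against a supplied rate bound, so arbitrary time-varying rates are exact;
extinct lineages are pruned, each extant tip is retained independently
with probability ``sampling_fraction``, and the result is conditioned on
at least two sampled tips by rejection with a retry cap.  The default
fixture scenario mirrors the study's scale (a few hundred sampled tips,
sampling fraction 0.26, crown age of order 50 Myr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloTree, RegimePaintedTree, TreeError

__all__ = [
    "SimConfig", "BisseParams", "SimulationError",
    "simulate_bd_tree", "simulate_yule_tree", "simulate_bisse",
    "simulate_mk", "simulate_bm", "simulate_ou",
    "simulate_occurrences", "simulate_abundance_sample",
]


class SimulationError(RuntimeError):
    """Stop condition unreachable within the retry cap."""


@dataclass(frozen=True)
class SimConfig:
    """Stop condition, sampling fraction and seed for tree simulation.

    Exactly one of ``n_taxa`` (extant sampled tip count) or ``crown_age``
    (Myr) must be set.  Identical configs give bit-identical output.
    """

    seed: int
    n_taxa: int = None
    crown_age: float = None
    sampling_fraction: float = 1.0
    retry_cap: int = 1000
    #: upper bound on per-lineage total event rate, required for
    #: time-varying rates (thinning bound); inferred for constant rates
    rate_bound: float = None

    def __post_init__(self):
        if (self.n_taxa is None) == (self.crown_age is None):
            raise ValueError("set exactly one of n_taxa or crown_age")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling_fraction must lie in (0, 1]")
        if self.n_taxa is not None and self.n_taxa < 2:
            raise ValueError("n_taxa must be at least 2")


@dataclass(frozen=True)
class BisseParams:
    """State-dependent diversification rates (/lineage/Myr)."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda0, self.lambda1, self.mu0, self.mu1,
                         self.q01, self.q10])

    def stationary_root_distribution(self) -> np.ndarray:
        q01, q10 = self.q01, self.q10
        if q01 + q10 == 0:
            return np.array([0.5, 0.5])
        return np.array([q10, q01]) / (q01 + q10)


# ---------------------------------------------------------------------------
# forward birth-death engine (1 or 2 character states)
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("parent", "birth", "end", "children", "segments", "alive")

    def __init__(self, parent, birth, state):
        self.parent = parent
        self.birth = birth
        self.end = None
        self.children = ()
        self.segments = [[state, birth]]  # [state, start_time]
        self.alive = True

    @property
    def state(self):
        return self.segments[-1][0]


def _forward_simulate(rng, lam, mu, q, root_states, stop_taxa, stop_age,
                      rate_bound):
    """One forward pass.  ``lam``, ``mu``: per-state callables of forward
    time; ``q``: 2x2 transition-rate matrix (or None for one state).
    Returns (lineages, present_time) or None on total extinction."""
    n_states = len(root_states)
    qrates = np.zeros((n_states, n_states)) if q is None else np.asarray(q, float)
    lineages = [_Lineage(-1, 0.0, s) for s in root_states]
    alive = set(range(len(lineages)))
    t = 0.0
    while True:
        if not alive:
            return None
        if stop_taxa is not None and len(alive) >= stop_taxa:
            # present set strictly between this event and the next one
            n = len(alive)
            dt = rng.exponential(1.0 / (n * rate_bound))
            present = t + rng.uniform(0.0, dt)
            break
        n = len(alive)
        t_next = t + rng.exponential(1.0 / (n * rate_bound))
        if stop_age is not None and t_next >= stop_age:
            present = stop_age
            break
        t = t_next
        i = rng.choice(np.fromiter(alive, dtype=np.int64, count=len(alive)))
        lin = lineages[i]
        s = lin.state
        rates = np.concatenate(([lam[s](t), mu[s](t)], qrates[s]))
        rates[2 + s] = 0.0
        total = rates.sum()
        u = rng.uniform(0.0, rate_bound)
        if u >= total:
            continue  # thinned (virtual) event
        kind = np.searchsorted(np.cumsum(rates), u, side="right")
        if kind == 0:  # speciation
            lin.end = t
            lin.alive = False
            c1 = _Lineage(i, t, s)
            c2 = _Lineage(i, t, s)
            lineages.extend([c1, c2])
            lin.children = (len(lineages) - 2, len(lineages) - 1)
            alive.discard(i)
            alive.update(lin.children)
        elif kind == 1:  # extinction
            lin.end = t
            lin.alive = False
            alive.discard(i)
        else:  # state transition
            lin.segments.append([kind - 2, t])
    for i in alive:
        lineages[i].end = present
    return lineages, present


def _reconstruct(lineages, present, sampled, label_prefix="t"):
    """Prune to sampled extant tips; returns (PhyloTree, paintings,
    tip_states) with per-branch state segments listed root-to-tip."""
    marked = set()
    for i in sampled:
        v = i
        while v >= 0 and v not in marked:
            marked.add(v)
            v = lineages[v].parent
    sampled_set = set(sampled)

    parent_l, length_l, label_l, paint_l = [], [], [], []

    def new_node(parent):
        parent_l.append(parent)
        length_l.append(0.0)
        label_l.append(None)
        paint_l.append(None)
        return len(parent_l) - 1

    tip_counter = [0]

    def build(i, node_parent, carried_segments):
        """carried_segments: state history from merged unary ancestors."""
        lin = lineages[i]
        segs = carried_segments + [
            (s, (lin.segments[k + 1][1] if k + 1 < len(lin.segments)
                 else lin.end) - start)
            for k, (s, start) in enumerate(lin.segments)]
        kept = [c for c in lin.children if c in marked]
        if not kept:  # sampled tip
            assert i in sampled_set
            v = new_node(node_parent)
            tip_counter[0] += 1
            label_l[v] = f"{label_prefix}{tip_counter[0]}"
            _attach(v, segs)
            return v
        if len(kept) == 1:
            return build(kept[0], node_parent, segs)
        v = new_node(node_parent)
        _attach(v, segs)
        for c in kept:
            build(c, v, [])
        return v

    def _attach(v, segs):
        merged = []
        for s, d in segs:
            if d <= 0 and merged:
                continue
            if merged and merged[-1][0] == s:
                merged[-1][1] += d
            else:
                merged.append([s, d])
        merged = [m for m in merged if m[1] > 0] or [merged[0]]
        paint_l[v] = [(s, d) for s, d in merged]
        length_l[v] = sum(d for _, d in merged)

    # find the MRCA of the sampled tips: walk from the initial lineages
    roots = [i for i, lin in enumerate(lineages)
             if lin.parent == -1 and i in marked]
    if len(roots) == 2:
        root = new_node(-1)
        for r in roots:
            build(r, root, [])
    else:
        # descend to the first node with two marked children
        i = roots[0]
        while True:
            kept = [c for c in lineages[i].children if c in marked]
            if len(kept) >= 2:
                break
            if not kept:  # single sampled tip - caller must prevent this
                raise SimulationError("fewer than two sampled tips")
            i = kept[0]
        root = new_node(-1)
        for c in [c for c in lineages[i].children if c in marked]:
            build(c, root, [])
    paint_l[root] = None
    tree = PhyloTree(np.array(parent_l), np.array(length_l), label_l, root)
    tip_states = {label_l[v]: paint_l[v][-1][0] for v in tree.tip_ids}
    return tree, paint_l, tip_states


def _as_rate_fn(r):
    if callable(r):
        return r
    v = float(r)
    return lambda t, v=v: v


def _run_conditioned(rng, lam, mu, q, root_state_sampler, config,
                     min_tips=2):
    lam = [_as_rate_fn(r) for r in lam]
    mu = [_as_rate_fn(r) for r in mu]
    bound = config.rate_bound
    if bound is None:
        # loose but safe bound for constant rates: sum of all state rates
        consts = [fn(0.0) for fn in lam + mu]
        qtot = 0.0 if q is None else float(np.asarray(q).sum())
        bound = sum(consts) + qtot
    if bound <= 0:
        raise ValueError("rate bound must be positive")
    for _ in range(config.retry_cap):
        root_states = root_state_sampler(rng)
        res = _forward_simulate(rng, lam, mu, q, root_states,
                                config.n_taxa, config.crown_age, bound)
        if res is None:
            continue
        lineages, present = res
        extant = [i for i, l in enumerate(lineages) if l.alive]
        if config.sampling_fraction < 1.0:
            keep = rng.random(len(extant)) < config.sampling_fraction
            sampled = [i for i, k in zip(extant, keep) if k]
        else:
            sampled = extant
        if len(sampled) < min_tips:
            continue
        return _reconstruct(lineages, present, sampled)
    raise SimulationError(
        f"no surviving simulation within {config.retry_cap} attempts")


def simulate_bd_tree(lam, mu, config: SimConfig) -> PhyloTree:
    """Reconstructed birth-death tree of extant, sampled tips.

    ``lam`` and ``mu`` are constants or callables of forward time from
    the crown (time-varying rates need ``config.rate_bound``).
    """
    rng = np.random.default_rng(config.seed)
    tree, _, _ = _run_conditioned(
        rng, [lam], [mu], None, lambda r: (0, 0), config)
    return tree


def simulate_yule_tree(lam: float, n_taxa: int, seed: int) -> PhyloTree:
    """Pure-birth tree with ``n_taxa`` tips (complete sampling)."""
    return simulate_bd_tree(lam, 0.0, SimConfig(seed=seed, n_taxa=n_taxa))


def simulate_bisse(params: BisseParams, config: SimConfig, root_state=None):
    """Tree plus binary tip states under state-dependent diversification.

    Returns (tree, tip_states, history) where ``history`` is the true
    lineage-state painting of the reconstructed tree (a
    :class:`RegimePaintedTree`), kept for diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    q = [[0.0, params.q01], [params.q10, 0.0]]
    pi = params.stationary_root_distribution()

    def sampler(r):
        s = root_state if root_state is not None else int(r.choice(2, p=pi))
        return (s, s)

    tree, paintings, tip_states = _run_conditioned(
        rng, [params.lambda0, params.lambda1], [params.mu0, params.mu1],
        q, sampler, config)
    history = RegimePaintedTree(tree, paintings, regimes=(0, 1))
    return tree, tip_states, history


# ---------------------------------------------------------------------------
# traits on a fixed tree
# ---------------------------------------------------------------------------

def simulate_mk(tree: PhyloTree, q01: float, q10: float, root_state: int,
                seed: int):
    """Two-state Markov trait on a fixed tree.

    Returns (tip_states, history); the history is a
    :class:`RegimePaintedTree` whose segments record the true path.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("transition rates must be nonnegative")
    rng = np.random.default_rng(seed)
    rates = {0: q01, 1: q10}
    paintings = [None] * tree.n_nodes
    node_state = np.empty(tree.n_nodes, dtype=int)
    node_state[tree.root] = root_state
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        remaining = tree.lengths[v]
        segs = []
        elapsed = 0.0
        while True:
            rate = rates[s]
            dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if elapsed + dt >= remaining:
                segs.append((s, remaining - elapsed))
                break
            segs.append((s, dt))
            elapsed += dt
            s = 1 - s
        if tree.lengths[v] == 0:
            segs = [(s, 0.0)]
        paintings[v] = segs
        node_state[v] = s
    history = RegimePaintedTree(tree, paintings, regimes=(0, 1))
    tip_states = {tree.labels[i]: int(node_state[i]) for i in tree.tip_ids}
    return tip_states, history


def simulate_bm(tree: PhyloTree, sigma2: float = 1.0, root_value: float = 0.0,
                seed=None, n_reps: int = 1, rng=None) -> np.ndarray:
    """Brownian tip values, shape (n_tips, n_reps), tip order = tip_ids."""
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.empty((tree.n_nodes, n_reps))
    X[tree.root] = root_value
    eps = rng.standard_normal((tree.n_nodes, n_reps))
    sd = np.sqrt(sigma2 * tree.lengths)
    for v in tree.preorder():
        p = tree.parent[v]
        if p >= 0:
            X[v] = X[p] + sd[v] * eps[v]
    tip_rows = {int(t): k for k, t in enumerate(tree.tip_ids)}
    out = np.empty((len(tip_rows), n_reps))
    for t, k in tip_rows.items():
        out[k] = X[t]
    return out


def simulate_ou(painted: RegimePaintedTree, alpha, sigma2, theta,
                root_value=None, seed=None, n_reps: int = 1,
                root_mode: str = "fixed") -> pd.DataFrame:
    """Ornstein-Uhlenbeck (or BM-limit) trait on a regime-painted tree.

    ``alpha``, ``sigma2``, ``theta`` map regime label -> parameter.
    Sampling is exact segment-by-segment: over a segment of duration d in
    regime r, X moves to theta_r + (X - theta_r) e^{-alpha_r d} plus
    Gaussian noise of variance sigma2_r (1 - e^{-2 alpha_r d})/(2 alpha_r)
    (Brownian limit sigma2_r d at alpha_r = 0).  Root value defaults to
    the root regime's optimum.

    Returns a DataFrame (index = tip labels, one column per replicate).
    """
    for r in painted.regimes:
        if sigma2[r] < 0 or alpha[r] < 0:
            raise ValueError("alpha and sigma2 must be nonnegative")
    tree = painted.tree
    rng = np.random.default_rng(seed)
    root_regime = painted.root_regime()
    if root_value is None:
        root_value = theta[root_regime]
    X = np.empty((tree.n_nodes, n_reps))
    if root_mode == "stationary" and alpha[root_regime] > 0:
        sd0 = np.sqrt(sigma2[root_regime] / (2 * alpha[root_regime]))
        X[tree.root] = root_value + sd0 * rng.standard_normal(n_reps)
    elif root_mode in ("fixed", "stationary"):
        X[tree.root] = root_value
    else:
        raise ValueError("root_mode must be 'fixed' or 'stationary'")
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        x = X[p].copy()
        for r, d in painted.paintings[v]:
            a, s2, th = alpha[r], sigma2[r], theta[r]
            if a > 0:
                e = np.exp(-a * d)
                mean = th + (x - th) * e
                var = s2 * (1 - e * e) / (2 * a)
            else:
                mean = x
                var = s2 * d
            x = mean + np.sqrt(var) * rng.standard_normal(n_reps)
        X[v] = x
    tips = tree.tip_ids
    return pd.DataFrame(X[tips], index=[tree.labels[i] for i in tips])


# ---------------------------------------------------------------------------
# occurrences and abundance samples
# ---------------------------------------------------------------------------

def simulate_occurrences(true_ranges: dict, n_stations: int = 10,
                         dredge_width: float = 50.0,
                         p_constant_depth: float = 0.3,
                         seed=None) -> pd.DataFrame:
    """Multi-station occurrence records around true depth ranges.

    Each record samples a true occurrence depth uniformly inside the
    species' interval, then reports a station interval extending it by
    uniform dredge margins up to ``dredge_width`` m on each side (clipped
    at the surface); with probability ``p_constant_depth`` the station is
    a constant-depth record instead.  Every station interval therefore
    contains at least one point of the true range.
    """
    rng = np.random.default_rng(seed)
    rows = []
    station = 0
    for sp in sorted(true_ranges):
        lo, hi = true_ranges[sp]
        if not (0 <= lo <= hi):
            raise ValueError(f"empty or invalid true range for {sp}")
        for _ in range(n_stations):
            station += 1
            x = rng.uniform(lo, hi)
            if rng.random() < p_constant_depth or dredge_width == 0:
                smin = smax = x
            else:
                smin = max(0.0, x - rng.uniform(0, dredge_width))
                smax = x + rng.uniform(0, dredge_width)
            rows.append({"species": sp, "station": f"st{station}",
                         "station_min_depth": round(smin, 1),
                         "station_max_depth": round(smax, 1)})
    return pd.DataFrame(rows)


def simulate_abundance_sample(true_richness: int, sample_size: int,
                              distribution: str = "logseries",
                              shape: float = 0.95, seed=None) -> pd.Series:
    """Sampled abundance counts from a community of ``true_richness``
    species.

    ``distribution``: "uniform" (equal relative abundances) or
    "logseries" (p_i proportional to shape**i / i, the classic
    few-dominants/many-rare structure that produces singletons and
    doubletons).  Returns counts indexed by species id, zeros omitted.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be at least 1")
    rng = np.random.default_rng(seed)
    i = np.arange(1, true_richness + 1, dtype=float)
    if distribution == "uniform":
        p = np.ones(true_richness)
    elif distribution == "logseries":
        p = shape ** i / i
    else:
        raise ValueError(f"unknown abundance distribution '{distribution}'")
    p /= p.sum()
    counts = rng.multinomial(sample_size, p)
    s = pd.Series(counts, index=[f"sp{j}" for j in range(1, true_richness + 1)])
    return s[s > 0]
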