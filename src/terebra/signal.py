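"""Phylogenetic signal and phylogenetic-diversity metrics.

Pagel's lambda rescales the off-diagonal of the phylogenetic covariance:
lambda = 1 keeps the Brownian expectation, lambda = 0 makes tips
independent.  The D statistic of binary traits compares the observed
sum of nodal character changes against two nulls - random tip shuffling
(D = 1) and threshold-coded Brownian evolution (D = 0).  Faith PD, MPD
and MNTD summarize the phylogenetic dispersion of a taxon set, and the
SES wrapper standardizes them against a tip-label randomization null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .simulate import simulate_bm
from .tree import PhyloTree, TreeError, vcv_matrix

__all__ = [
    "SignalResult", "DStatResult", "SesResult",
    "pagels_lambda", "fritz_purvis_d", "faith_pd",
    "patristic_distances", "mpd", "mntd", "ses_metric",
]


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalResult:
    lam: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    sigma2: float
    root_mean: float


def _gls_loglik(V: np.ndarray, x: np.ndarray):
    """Profile the root mean and sigma^2 out of the Gaussian likelihood."""
    n = x.size
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError as exc:
        raise TreeError(f"singular phylogenetic covariance: {exc}") from exc
    ones = np.ones(n)
    Vi1 = linalg.cho_solve((c, low), ones, check_finite=False)
    Vix = linalg.cho_solve((c, low), x, check_finite=False)
    mu = (ones @ Vix) / (ones @ Vi1)
    r = x - mu
    s2 = (r @ linalg.cho_solve((c, low), r, check_finite=False)) / n
    logdet = 2 * np.sum(np.log(np.diag(c)))
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, s2, mu


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal shared path lengths by lambda, keep the diagonal."""
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def pagels_lambda(tree: PhyloTree, trait) -> SignalResult:
    """ML estimate of Pagel's lambda on [0, 1] by profiled GLS.

    ``trait`` maps species -> value (dict or pandas Series) or is an
    array in ``tree.tip_ids`` order.
    """
    x = _tip_vector(tree, trait)
    if x.size < 4:
        raise ValueError("Pagel's lambda needs at least 4 species")
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    V = vcv_matrix(tree)
    if tree.height <= 0:
        raise TreeError("tree has zero height")

    def nll(lam):
        return -_gls_loglik(lambda_transform(V, lam), x)[0]

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [0.0, 1.0, float(res.x)]
    lls = [-nll(l) for l in candidates]
    best = int(np.argmax(lls))
    lam_hat = candidates[best]
    ll_hat, s2, mu = _gls_loglik(lambda_transform(V, lam_hat), x)
    return SignalResult(lam=lam_hat, loglik=ll_hat,
                        loglik_lambda0=lls[0], loglik_lambda1=lls[1],
                        sigma2=s2, root_mean=mu)


def _tip_vector(tree: PhyloTree, trait) -> np.ndarray:
    if isinstance(trait, (dict,)):
        return np.array([trait[l] for l in tree.tip_labels], dtype=float)
    if hasattr(trait, "reindex"):  # pandas Series
        return trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    return np.asarray(trait, dtype=float)


# ---------------------------------------------------------------------------
# Fritz-Purvis D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DStatResult:
    d: float
    sum_changes_obs: float
    null_random_mean: float
    null_random_sd: float
    null_brownian_mean: float
    null_brownian_sd: float
    p_random: float
    p_brownian: float
    n_null: int


def _sum_of_changes(tree: PhyloTree, values: np.ndarray) -> np.ndarray:
    """Sum over edges of |parent - child| after assigning each internal
    node the unweighted mean of its children.  ``values``: (n_tips, m)
    in tip_ids order; returns (m,) sums, vectorized across columns."""
    vals = np.zeros((tree.n_nodes,) + values.shape[1:])
    tip_rows = {int(t): k for k, t in enumerate(tree.tip_ids)}
    for t, k in tip_rows.items():
        vals[t] = values[k]
    for v in tree.postorder():
        kids = tree.children[v]
        if kids:
            vals[v] = np.mean([vals[c] for c in kids], axis=0)
    total = np.zeros(values.shape[1:])
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            total += np.abs(vals[p] - vals[v])
    return total


def fritz_purvis_d(tree: PhyloTree, states, n_null: int = 1000,
                   seed=None) -> DStatResult:
    """D statistic for a binary trait with permutation and
    Brownian-threshold nulls.

    D = (sum_obs - mean sum_B) / (mean sum_R - mean sum_B); ~1 for a
    phylogenetically random trait, ~0 for Brownian-threshold clumping.
    Monte-Carlo p-values use the (count + 1)/(n + 1) correction.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    x = _tip_vector(tree, states)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("states must be binary 0/1")
    n1 = int(x.sum())
    n = x.size
    if n1 == 0 or n1 == n:
        raise ValueError("D is undefined for a monomorphic trait")
    rng = np.random.default_rng(seed)

    d_obs = float(_sum_of_changes(tree, x[:, None])[0])

    # permutation null: shuffle tip states
    perm = np.empty((n, n_null))
    for j in range(n_null):
        perm[:, j] = rng.permutation(x)
    d_rand = _sum_of_changes(tree, perm)

    # Brownian null: BM tips thresholded at the observed prevalence.
    # Antithetic pairs (Z, -Z) make the null exactly invariant under the
    # 0/1 complement of the trait and reduce Monte-Carlo variance.
    half = (n_null + 1) // 2
    bm_half = simulate_bm(tree, sigma2=1.0, n_reps=half, rng=rng)
    bm = np.concatenate([bm_half, -bm_half], axis=1)[:, :n_null]
    order = np.argsort(bm, axis=0)
    thresh = np.zeros_like(bm)
    rows = order[-n1:, :]
    np.put_along_axis(thresh, rows, 1.0, axis=0)
    d_brown = _sum_of_changes(tree, thresh)

    mean_r, mean_b = float(d_rand.mean()), float(d_brown.mean())
    d = (d_obs - mean_b) / (mean_r - mean_b)
    p_rand = (np.sum(d_rand <= d_obs) + 1) / (n_null + 1)
    p_brown = (np.sum(d_brown <= d_obs) + 1) / (n_null + 1)
    return DStatResult(
        d=float(d), sum_changes_obs=d_obs,
        null_random_mean=mean_r, null_random_sd=float(d_rand.std()),
        null_brownian_mean=mean_b, null_brownian_sd=float(d_brown.std()),
        p_random=float(p_rand), p_brownian=float(p_brown), n_null=n_null)


# ---------------------------------------------------------------------------
# PD / MPD / MNTD with SES
# ---------------------------------------------------------------------------

def faith_pd(tree: PhyloTree, taxa, include_root: bool = True) -> float:
    """Faith's PD: branch-length sum of the minimal spanning subtree.

    By default the path to the root is included (rooted-PD convention),
    so a single taxon has PD equal to its root-to-tip depth.
    """
    idx = tree.tip_index()
    taxa = list(taxa)
    unknown = [t for t in taxa if t not in idx]
    if unknown:
        raise TreeError(f"unknown taxa: {unknown}")
    if not taxa:
        raise ValueError("taxon set must be nonempty")
    marked = np.zeros(tree.n_nodes, dtype=bool)
    for t in taxa:
        v = idx[t]
        while v >= 0 and not marked[v]:
            marked[v] = True
            v = tree.parent[v]
    if include_root:
        marked[tree.root] = False  # root has no branch above
        return float(tree.lengths[marked].sum())
    # drop the chain from the root down to (and including) the set's MRCA
    v = tree.root
    while True:
        kids = [c for c in tree.children[v] if marked[c]]
        marked[v] = False
        if len(kids) != 1:
            break
        v = kids[0]
    return float(tree.lengths[marked].sum())


def patristic_distances(tree: PhyloTree) -> np.ndarray:
    """Tip-to-tip path lengths (tip_ids order)."""
    depths = tree.depths()
    td = depths[tree.tip_ids]
    M = tree.mrca_matrix()
    return td[:, None] + td[None, :] - 2 * depths[M]


def mpd(dist: np.ndarray, rows) -> float:
    """Mean pairwise distance over unordered pairs of ``rows``."""
    rows = np.asarray(rows)
    if rows.size < 2:
        raise ValueError("MPD needs at least 2 taxa")
    sub = dist[np.ix_(rows, rows)]
    iu = np.triu_indices(rows.size, k=1)
    return float(sub[iu].mean())


def mntd(dist: np.ndarray, rows) -> float:
    """Mean nearest-taxon distance within ``rows``."""
    rows = np.asarray(rows)
    if rows.size < 2:
        raise ValueError("MNTD needs at least 2 taxa")
    sub = dist[np.ix_(rows, rows)].astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass(frozen=True)
class SesResult:
    metric: str
    community: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_rand: int


def ses_metric(tree: PhyloTree, communities: dict, metric: str = "MPD",
               n_rand: int = 999, seed=None, include_root: bool = True):
    """Standardized effect sizes of PD, MPD or MNTD per community.

    The null shuffles tip labels across the whole tree holding community
    sizes fixed ("taxa.labels"-style); z = (obs - null mean)/null SD and
    p is the null quantile with the (count + 1)/(n + 1) correction.
    """
    if metric not in ("PD", "MPD", "MNTD"):
        raise ValueError("metric must be PD, MPD or MNTD")
    if n_rand < 100:
        warnings.warn("fewer than 100 randomizations gives coarse p-values",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    pos = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    dist = patristic_distances(tree) if metric in ("MPD", "MNTD") else None

    def observe(rows, names):
        if metric == "PD":
            return faith_pd(tree, names, include_root=include_root)
        fn = mpd if metric == "MPD" else mntd
        return fn(dist, rows)

    results = {}
    for name, taxa in communities.items():
        taxa = list(taxa)
        if not taxa:
            raise ValueError(f"community '{name}' is empty")
        if metric in ("MPD", "MNTD") and len(taxa) < 2:
            raise ValueError(
                f"community '{name}' needs >= 2 taxa for {metric}")
        rows = np.array([pos[t] for t in taxa])
        obs = observe(rows, taxa)
        null = np.empty(n_rand)
        k = len(taxa)
        for j in range(n_rand):
            rnd = rng.choice(n, size=k, replace=False)
            null[j] = observe(rnd, [labels[i] for i in rnd])
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        z = (obs - mu) / sd
        p = (np.sum(null <= obs) + 1) / (n_rand + 1)
        results[name] = SesResult(metric=metric, community=name,
                                  observed=float(obs), null_mean=mu,
                                  null_sd=sd, z=float(z), p=float(p),
                                  n_rand=n_rand)
    return results
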