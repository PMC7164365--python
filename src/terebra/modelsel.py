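"""Information-criterion bookkeeping shared by every model-fitting stage.

AIC = 2k - 2 logL; AICc adds the small-sample correction
2k(k+1)/(n-k-1); Akaike weights are normalized relative likelihoods
within a declared model set.  The study's decision rule declares a single
winner only when the runner-up's dAIC exceeds 2 *and* the winner's
weight exceeds 0.5; anything else is reported as ambiguous.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelFit", "aic_weights", "model_table", "select_model",
           "data_checksum"]


@dataclass
class ModelFit:
    """One fitted model: estimates, log-likelihood and diagnostics."""

    name: str
    params: dict
    loglik: float
    k: int
    n: int
    converged: bool = True
    hessian_eigenvalues: np.ndarray = None
    diagnostics: dict = field(default_factory=dict)
    data_id: str = None

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def aicc(self) -> float:
        denom = self.n - self.k - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2 * self.k * (self.k + 1) / denom

    @property
    def hessian_positive(self):
        if self.hessian_eigenvalues is None:
            return None
        return bool(np.all(np.asarray(self.hessian_eigenvalues) > 0))


def data_checksum(*arrays) -> str:
    """Stable fingerprint of the data a set of fits was computed on."""
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, str):
            h.update(a.encode())
        else:
            h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def aic_weights(scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    d = scores - scores.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def model_table(fits, criterion: str = "aic"):
    """Rank fits by AIC or AICc; returns list of row dicts (best first)."""
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    scores = np.array([getattr(f, criterion) for f in fits])
    w = aic_weights(scores)
    order = np.argsort(scores, kind="stable")
    rows = []
    for rank, i in enumerate(order):
        f = fits[i]
        rows.append({
            "model": f.name, "logL": f.loglik, "k": f.k,
            "aic": f.aic, "aicc": f.aicc,
            "delta": scores[i] - scores.min(), "weight": w[i],
            "converged": f.converged, "params": f.params,
        })
    return rows


def select_model(fits, criterion: str = "aic",
                 delta_threshold: float = 2.0, weight_threshold: float = 0.5):
    """Apply the dAIC > 2 and weight > 0.5 rule over a model set.

    Returns a dict with the ranked table, the best model's name, and
    ``decision`` in {"winner", "ambiguous"}.  Fits computed on different
    data (per their ``data_id``) are rejected.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("select_model needs at least two fits")
    ids = {f.data_id for f in fits if f.data_id is not None}
    if len(ids) > 1:
        raise ValueError("fits were computed on different data")
    rows = model_table(fits, criterion)
    runner_delta = rows[1]["delta"]
    best = rows[0]
    decisive = runner_delta > delta_threshold and best["weight"] > weight_threshold
    return {
        "criterion": criterion,
        "table": rows,
        "best": best["model"],
        "runner_up_delta": runner_delta,
        "best_weight": best["weight"],
        "decision": "winner" if decisive else "ambiguous",
    }
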