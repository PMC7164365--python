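"""Occurrence-based data coding and diversity extrapolation.

Implements the study-style coding computations: Chao1 richness with its
bias-corrected fallback, the two-step extrapolation of global richness
from a densely sampled reference region (here the Indo-Pacific), trait
state-specific sampling fractions for state-dependent diversification,
the conservative depth-range algorithm, and the binarizations of depth
(100 m), shell size (25 mm) and larval ecology (protoconch whorls).

The depth-range rule is deliberately conservative: the species minimum
depth is the lowest *maximum* station depth (so at least one specimen was
certainly at that depth or shallower) and the species maximum is the
highest *minimum* station depth.  Constant-depth stations contribute
their single depth to both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversitySample", "Chao1Result", "DepthRange",
    "chao1", "diversity_sample_from_counts", "estimate_total_diversity",
    "state_sampling_fractions", "species_depth_range", "depth_ranges_from_table",
    "code_depth_binary", "code_size_binary", "classify_protoconch",
]


@dataclass(frozen=True)
class DiversitySample:
    """Observed richness with singleton/doubleton counts for one region."""

    s_obs: int
    f1: int
    f2: int
    region: str = ""

    def __post_init__(self):
        for name in ("s_obs", "f1", "f2"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.f1 + self.f2 > self.s_obs:
            raise ValueError("f1 + f2 cannot exceed S_obs")


@dataclass(frozen=True)
class Chao1Result:
    estimate: float
    s_obs: int
    f1: int
    f2: int
    bias_corrected: bool


def diversity_sample_from_counts(counts, region: str = "") -> DiversitySample:
    """Build a :class:`DiversitySample` from per-species abundance counts."""
    counts = np.asarray(list(counts.values()) if isinstance(counts, dict)
                        else counts, dtype=int)
    counts = counts[counts > 0]
    return DiversitySample(
        s_obs=int(counts.size),
        f1=int(np.sum(counts == 1)),
        f2=int(np.sum(counts == 2)),
        region=region,
    )


def chao1(sample: DiversitySample) -> Chao1Result:
    """Chao1 estimated richness: S_obs + f1^2 / (2 f2).

    With no doubletons the bias-corrected form
    S_obs + f1 (f1 - 1) / (2 (f2 + 1)) is used and flagged.
    """
    s, f1, f2 = sample.s_obs, sample.f1, sample.f2
    if f2 > 0:
        return Chao1Result(s + f1 ** 2 / (2 * f2), s, f1, f2, False)
    return Chao1Result(s + f1 * (f1 - 1) / (2 * (f2 + 1)), s, f1, f2, True)


def estimate_total_diversity(ip_sample: DiversitySample, worms_described: int,
                             newly_delimited: int = 0) -> dict:
    """Two-step global richness extrapolation.

    The Chao1 / S_obs ratio of the reference (Indo-Pacific) sample is
    taken as region-independent sampling effectiveness, applied to the
    count of described species, and newly delimited species are added.
    """
    if worms_described <= 0:
        raise ValueError("worms_described must be positive")
    if ip_sample.s_obs == 0:
        raise ValueError("reference sample has no observed species")
    c = chao1(ip_sample)
    ratio = c.estimate / ip_sample.s_obs
    total = ratio * worms_described + newly_delimited
    return {
        "ratio": ratio,
        "total": total,
        "chao1": c.estimate,
        "chao1_bias_corrected": c.bias_corrected,
        "s_obs": ip_sample.s_obs,
        "f1": ip_sample.f1,
        "f2": ip_sample.f2,
        "worms_described": worms_described,
        "newly_delimited": newly_delimited,
        "region": ip_sample.region,
    }


def state_sampling_fractions(ip_state_counts, total_diversity: float,
                             sampled_counts) -> tuple:
    """State-specific sampling fractions for a binary trait.

    The reference-region state ratio n_k / (n0 + n1) partitions the total
    estimated richness into per-state richness; each sampling fraction is
    the number of sampled (in-tree) species of that state divided by its
    estimated richness, clipped into (0, 1] with a warning.
    """
    n0, n1 = ip_state_counts
    s0, s1 = sampled_counts
    if total_diversity <= 0:
        raise ValueError("total_diversity must be positive")
    if n0 + n1 <= 0:
        raise ValueError("reference state counts are empty")
    fractions = []
    for nk, sk in ((n0, s0), (n1, s1)):
        est = total_diversity * nk / (n0 + n1)
        f = sk / est if est > 0 else np.nan
        if f > 1:
            warnings.warn(
                f"sampled count {sk} exceeds estimated state richness "
                f"{est:.1f}; clipping sampling fraction to 1", stacklevel=2)
            f = 1.0
        fractions.append(f)
    return tuple(fractions)


@dataclass(frozen=True)
class DepthRange:
    min_depth: float
    max_depth: float
    confidence: str = "ok"  # "ok" | "wide-station"
    n_records: int = 0


def species_depth_range(records) -> DepthRange:
    """Conservative depth range from (station_min, station_max) intervals.

    species_min = min over stations of station_max;
    species_max = max over stations of station_min.  A single broad
    dredge can invert the pair; then the ordered interval is returned
    flagged "wide-station".
    """
    records = [(float(lo), float(hi)) for lo, hi in records]
    if not records:
        raise ValueError("species has no occurrence records")
    for lo, hi in records:
        if lo < 0 or lo > hi:
            raise ValueError(f"bad station interval ({lo}, {hi})")
    smin = min(hi for _, hi in records)
    smax = max(lo for lo, _ in records)
    if smin > smax:
        return DepthRange(smax, smin, "wide-station", len(records))
    return DepthRange(smin, smax, "ok", len(records))


def depth_ranges_from_table(occ: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`species_depth_range` per species of an occurrence table."""
    rows = []
    for sp, grp in occ.groupby("species", sort=True):
        r = species_depth_range(
            zip(grp["station_min_depth"], grp["station_max_depth"]))
        rows.append({"species": sp, "depth_min_m": r.min_depth,
                     "depth_max_m": r.max_depth, "confidence": r.confidence,
                     "n_records": r.n_records})
    return pd.DataFrame(rows).set_index("species")


def code_depth_binary(depth_range, threshold: float = 100.0) -> int:
    """0 = shallow (species minimum depth <= threshold), 1 = deep."""
    if isinstance(depth_range, DepthRange):
        smin = depth_range.min_depth
    else:
        smin = float(depth_range[0])
    return 0 if smin <= threshold else 1


def code_size_binary(sizes, threshold: float = 25.0):
    """0 = small (length <= threshold mm), 1 = large (strictly exceeding).

    Returns (states, report); the report carries the empirical 25th
    percentile and the fraction of species the threshold accommodates.
    """
    s = pd.Series(sizes, dtype=float)
    if (s <= 0).any():
        raise ValueError("shell sizes must be positive")
    states = (s > threshold).astype(int)
    report = {
        "threshold_mm": threshold,
        "quartile_25_mm": float(np.percentile(s.to_numpy(), 25)),
        "fraction_small": float((states == 0).mean()),
        "n_species": int(s.size),
    }
    return states, report


PLANKTOTROPHIC = "planktotrophic"
LECITHOTROPHIC = "lecithotrophic"
NEEDS_MANUAL = "needs_manual"


def classify_protoconch(whorls: float, nucleus_small=None) -> str:
    """Larval ecology from protoconch whorl count (nearest quarter whorl).

    Multispiral protoconchs (>= 3 whorls) indicate feeding pelagic larvae
    (planktotrophy); paucispiral ones (<= 2.25) indicate yolk-provisioned
    larvae (lecithotrophy).  The intermediate 2.5-whorl morphology is
    resolved by nucleus size when recorded, else deferred to manual
    examination.
    """
    if whorls <= 0:
        raise ValueError("whorl count must be positive")
    q = whorls * 4
    if abs(q - round(q)) > 1e-9:
        raise ValueError("whorls must be counted to the nearest quarter whorl")
    if whorls >= 3:
        return PLANKTOTROPHIC
    if whorls <= 2.25:
        return LECITHOTROPHIC
    if nucleus_small is None:
        return NEEDS_MANUAL
    return PLANKTOTROPHIC if nucleus_small else LECITHOTROPHIC
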