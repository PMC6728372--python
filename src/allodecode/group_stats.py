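"""Group-level inference on per-participant decoding accuracies.

The group statistic is the mean accuracy over participants. Its sampling
distribution is characterised by a with-replacement bootstrap (default
B = 10,000), summarised by a bias-corrected and accelerated (BCa) confidence
interval. Significance against the 4-way chance level (25%) uses a shifted
Monte Carlo null: each participant's score is shifted by (chance - group
mean), so the shifted sample has mean exactly at chance while keeping the
empirical spread; the one-tailed p-value is

    p = (#{bootstrap null means >= observed group mean} + 1) / (B + 1),

where ties count against the alternative and the +1/+1 guards the case of
zero exceedances. For ROIs without a directed prior hypothesis, a Bonferroni
adjusted alpha (alpha / m) is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "GroupResult",
    "bootstrap_means",
    "bca_interval",
    "monte_carlo_p",
    "bonferroni_alpha",
    "CHANCE_4WAY",
]

CHANCE_4WAY = 0.25
DEFAULT_B = 10_000


@dataclass
class GroupResult:
    """Observed group decoding accuracy with bootstrap null summary."""

    roi: str
    factor: str
    n: int
    observed_mean: float
    B: int
    exceed_count: int
    p_value: float
    bca_ci: tuple[float, float]
    ci_level: float
    chance: float
    boot_seed: int
    null_histogram: tuple | None = None  # (counts, bin_edges), 100 bins

    def validate(self) -> None:
        if not (1 / (self.B + 1) <= self.p_value <= 1):
            raise ValueError("p-value out of bounds")
        if abs(self.p_value - (self.exceed_count + 1) / (self.B + 1)) > 1e-12:
            raise ValueError("p-value inconsistent with exceed count")
        if self.bca_ci[0] > self.bca_ci[1]:
            raise ValueError("CI endpoints out of order")

    def to_dict(self) -> dict:
        d = {
            "roi": self.roi,
            "factor": self.factor,
            "n": self.n,
            "observed_mean": self.observed_mean,
            "B": self.B,
            "exceed_count": self.exceed_count,
            "p_value": self.p_value,
            "bca_ci": list(self.bca_ci),
            "ci_level": self.ci_level,
            "chance": self.chance,
            "boot_seed": self.boot_seed,
        }
        if self.null_histogram is not None:
            counts, edges = self.null_histogram
            d["null_histogram"] = {"counts": list(counts), "bin_edges": list(edges)}
        return d


def _check_values(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    return values


def bootstrap_means(values, B: int = DEFAULT_B, seed: int = 0) -> np.ndarray:
    """B means of with-replacement resamples of the input sample."""
    values = _check_values(values)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    return values[idx].mean(axis=1)


def bca_interval(
    values, B: int = DEFAULT_B, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for the sample mean.

    The bias correction z0 comes from the fraction of bootstrap means below
    the observed mean; the acceleration a from the jackknife skewness of the
    leave-one-out means. The returned endpoints are the adjusted percentiles
    of the bootstrap distribution. A constant sample yields the degenerate
    interval (c, c) with a warning.
    """
    values = _check_values(values)
    obs = values.mean()
    if np.ptp(values) == 0:
        warnings.warn("all values identical; degenerate BCa interval", stacklevel=2)
        return (float(obs), float(obs))
    boots = bootstrap_means(values, B=B, seed=seed)
    # bias correction
    prop = np.mean(boots < obs)
    prop = min(max(prop, 1 / (2 * B)), 1 - 1 / (2 * B))  # keep z0 finite
    z0 = norm.ppf(prop)
    # acceleration from jackknife
    n = len(values)
    jack = (values.sum() - values) / (n - 1)
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    a = (dev**3).sum() / (6 * denom) if denom > 0 else 0.0
    alpha = (1 - level) / 2
    lo_hi = []
    for q in (alpha, 1 - alpha):
        z = z0 + norm.ppf(q)
        adj = norm.cdf(z0 + z / (1 - a * z))
        lo_hi.append(float(np.quantile(boots, adj)))
    return (lo_hi[0], lo_hi[1])


def monte_carlo_p(
    values,
    chance: float = CHANCE_4WAY,
    B: int = DEFAULT_B,
    seed: int = 0,
    roi: str = "roi",
    factor: str = "factor",
    ci_level: float = 0.95,
    keep_histogram: bool = False,
) -> GroupResult:
    """Shifted-null Monte Carlo significance test of mean accuracy > chance.

    The null sample is ``values - mean(values) + chance``; exceedances are
    bootstrap null means >= the observed mean, and
    p = (exceedances + 1) / (B + 1). The reported CI is the BCa interval of
    the (unshifted) observed sample, computed on an independent substream of
    the same seed.
    """
    values = _check_values(values)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    obs = float(values.mean())
    null_values = values - obs + chance
    seeds = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    null_means = bootstrap_means(null_values, B=B, seed=int(seeds[0]))
    exceed = int(np.sum(null_means >= obs))
    p = (exceed + 1) / (B + 1)
    if np.ptp(values) == 0:
        ci = (obs, obs)
    else:
        ci = bca_interval(values, B=B, level=ci_level, seed=int(seeds[1]))
    hist = None
    if keep_histogram:
        counts, edges = np.histogram(null_means, bins=100)
        hist = (counts.tolist(), edges.tolist())
    result = GroupResult(
        roi=roi,
        factor=factor,
        n=len(values),
        observed_mean=obs,
        B=B,
        exceed_count=exceed,
        p_value=p,
        bca_ci=ci,
        ci_level=ci_level,
        chance=chance,
        boot_seed=seed,
        null_histogram=hist,
    )
    result.validate()
    return result


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted per-comparison alpha (alpha / m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
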