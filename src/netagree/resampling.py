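"""Bootstrap estimators of the global integration score.

The unit of resampling is the agency-level score: a network yields one
score per agency and perspective, and the global score is their mean.
Three resampling schemes quantify its uncertainty:

* **standard** — B i.i.d. with-replacement resamples of the n scores; the
  point estimate is bias-corrected, 2*mean(s) - mean of replicate means.
* **balanced** — B copies of the score vector are concatenated, permuted
  once uniformly at random, and split consecutively into B resamples of
  size n, so every score appears exactly B times overall; this removes the
  Monte-Carlo component of the bootstrap bias estimate.
* **bayes** — each replicate draws flat-Dirichlet weights over the n scores
  (via sorted-uniform spacings) and records the weighted mean; the replicate
  distribution approximates a posterior for the global score, summarised by
  its mean and a central credibility interval.

Standard and balanced replicates are summarised by a bias-corrected and
accelerated (BCa) interval, which adjusts the percentile interval for median
bias (z0, from the share of replicates below the sample mean) and for
skewness (acceleration a, from jackknife leave-one-out means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "bootstrap_standard",
    "bootstrap_balanced",
    "bootstrap_bayes",
    "compute_bca",
]

MIN_REPLICATES = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate distribution and summary for one bootstrap run."""

    method: str  # standard | balanced | bayes
    point: float
    replicate_means: np.ndarray = field(repr=False)
    interval: tuple[float, float]
    interval_kind: str  # bca | credible
    B: int
    seed: int
    confidence: float

    def __post_init__(self) -> None:
        if self.interval[0] > self.interval[1]:
            raise ValueError("interval endpoints out of order")
        if len(self.replicate_means) != self.B:
            raise ValueError("replicate_means length must equal B")


def _check_inputs(scores: np.ndarray, B: int) -> None:
    if scores.size < 2:
        raise ValueError("bootstrap needs >= 2 agency scores")
    if B < MIN_REPLICATES:
        raise ValueError(
            f"B={B} is too small for a stable interval; use B >= {MIN_REPLICATES}"
        )
    if np.any(~np.isfinite(scores)) or np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be fractions in [0, 1]")


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def compute_bca(
    scores: Sequence[float],
    replicate_means: np.ndarray,
    sample_mean: float,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval endpoints.

    z0 is the normal quantile of the proportion of replicate means strictly
    below the sample mean; the acceleration a comes from the jackknife
    leave-one-out means m_i of the original scores,

        a = sum((mbar - m_i)^3) / (6 * [sum((mbar - m_i)^2)]^(3/2)).

    The endpoints are the empirical quantiles of the replicate means at the
    adjusted tail probabilities  Phi(z0 + (z0 + z_k) / (1 - a (z0 + z_k)))
    for z_k = +/- Phi^{-1}((1 + confidence) / 2).

    Degenerate replicate sets collapse to a point interval.  When every
    replicate mean falls strictly on one side of the sample mean the bias
    correction is unidentified; the central percentile interval is returned
    with a logged warning.
    """
    reps = np.asarray(replicate_means, dtype=float)
    if reps.size == 0:
        raise ValueError("no replicate means")
    if np.ptp(reps) == 0.0:
        return (float(reps[0]), float(reps[0]))

    alpha = (1.0 - confidence) / 2.0
    prop = float(np.mean(reps < sample_mean))
    if prop == 0.0 or prop == 1.0:
        logger.warning(
            "all replicate means on one side of the sample mean; "
            "falling back to the percentile interval"
        )
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
        return (float(lo), float(hi))
    z0 = float(stats.norm.ppf(prop))

    jack = np.asarray(scores, dtype=float)
    n = jack.size
    loo = (jack.sum() - jack) / (n - 1)  # leave-one-out means
    d = loo.mean() - loo
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    zlo = float(stats.norm.ppf(alpha))
    zhi = float(stats.norm.ppf(1.0 - alpha))
    endpoints = []
    for zk in (zlo, zhi):
        t = z0 + zk
        adj = stats.norm.cdf(z0 + t / (1.0 - a * t))
        endpoints.append(float(np.quantile(reps, adj)))
    return (min(endpoints), max(endpoints))


def bootstrap_standard(
    scores: Sequence[float],
    B: int = 40_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Standard i.i.d. bootstrap with bias-corrected point and BCa interval."""
    s = np.asarray(scores, dtype=float)
    _check_inputs(s, B)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, s.size, size=(B, s.size))
    reps = s[idx].mean(axis=1)
    sample_mean = float(s.mean())
    point = _clip01(2.0 * sample_mean - float(reps.mean()))
    interval = compute_bca(s, reps, sample_mean, confidence)
    return BootstrapResult(
        "standard", point, reps, interval, "bca", B, seed, confidence
    )


def balanced_resample_indices(
    n: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, n) resample index sets in which every observation index appears
    exactly B times overall: B copies of 0..n-1 are concatenated, permuted
    uniformly once, and split consecutively into B rows."""
    pool = np.tile(np.arange(n), B)
    rng.shuffle(pool)
    return pool.reshape(B, n)


def bootstrap_balanced(
    scores: Sequence[float],
    B: int = 40_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Balanced bootstrap: every score appears exactly B times overall.

    By construction the grand mean of the replicate means equals the sample
    mean (up to floating-point summation error), so the bias-corrected point
    estimate coincides with the sample mean apart from rounding.
    """
    s = np.asarray(scores, dtype=float)
    _check_inputs(s, B)
    rng = np.random.default_rng(seed)
    idx = balanced_resample_indices(s.size, B, rng)
    reps = s[idx].mean(axis=1)
    sample_mean = float(s.mean())
    point = _clip01(2.0 * sample_mean - float(reps.mean()))
    interval = compute_bca(s, reps, sample_mean, confidence)
    return BootstrapResult(
        "balanced", point, reps, interval, "bca", B, seed, confidence
    )


def bootstrap_bayes(
    scores: Sequence[float],
    B: int = 40_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Bayesian bootstrap: Dirichlet(1,...,1)-weighted means as posterior draws.

    Weights are generated by the sorted-uniform spacings construction: n-1
    uniforms are sorted and the gaps between 0, the order statistics and 1
    are the n weights.  The point estimate is the posterior mean and the
    interval the central credibility interval of the replicate draws.
    """
    s = np.asarray(scores, dtype=float)
    _check_inputs(s, B)
    rng = np.random.default_rng(seed)
    if np.ptp(s) == 0.0:  # posterior is degenerate at the common value
        reps = np.full(B, s[0])
    else:
        u = np.sort(rng.random(size=(B, s.size - 1)), axis=1)
        w = np.diff(u, axis=1, prepend=0.0, append=1.0)
        reps = w @ s
    point = float(reps.mean())
    alpha = (1.0 - confidence) / 2.0
    if np.ptp(reps) == 0.0:
        interval = (float(reps[0]), float(reps[0]))
    else:
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
        interval = (float(lo), float(hi))
    return BootstrapResult(
        "bayes", _clip01(point), reps, interval, "credible", B, seed, confidence
    )
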