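"""Synthetic service networks with known agreement structure.

Real inter-agency involvement surveys are confidential, so estimators are
exercised on generated networks whose true per-perspective agreement levels
are available in closed form.  Two generative models are provided:

* **independent** — every off-diagonal cell draws its expected rating from
  ``rating_distribution``; with probability ``agreement_prob`` (theta) the
  perceived rating in the same cell is set equal, otherwise it is drawn
  uniformly from the remaining categories.  Cells are mutually independent,
  so same-cell agreement (P1, P4) is exactly theta while cross-cell
  agreement (P2, P3) follows from the perceived and expected marginals.
* **consensus** — each unordered dyad of agencies carries one latent true
  involvement rating; all four observed values touching the dyad (perceived
  and expected, from both sides) report the latent value with probability
  ``1 - consensus_noise`` and a uniformly-chosen other category otherwise.
  Every perspective then shares the same closed-form agreement level.

After filling the matrices, each agency is independently marked
non-respondent with probability ``1 - response_rate`` and its column is
blanked in both matrices, reproducing the survey's structural asymmetry:
non-respondents keep a P1 score but lose P2–P4.

:func:`expected_scores` enumerates the generative joint distribution over
the category lattice and returns the exact expected agreement fraction per
perspective — the analytic oracle used in parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import RatingMatrixPair, RatingScale

__all__ = [
    "SyntheticConfig",
    "generate",
    "expected_scores",
    "SIMCOE_RESPONSE_RATE",
    "YORK_RESPONSE_RATE",
]

# Observed survey response rates offered as presets.
SIMCOE_RESPONSE_RATE = 0.89
YORK_RESPONSE_RATE = 0.64


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic network.

    Parameters
    ----------
    n_agencies
        Network size (the motivating surveys had 27 and 36 agencies).
    rating_distribution
        Probability of each ordinal category for expected / latent ratings;
        length must equal the scale's category count.  Defaults to uniform.
    agreement_prob
        theta, the probability that a perceived rating equals its same-cell
        expected rating (independent model only).
    response_rate
        Probability that an agency responds; non-respondents get an
        all-missing column.
    model
        "independent" or "consensus".
    consensus_noise
        Per-value probability of deviating from the dyad's latent rating
        (consensus model only).
    seed
        Seed for the generator's private random stream.
    """

    n_agencies: int = 30
    rating_distribution: tuple[float, ...] | None = None
    agreement_prob: float = 0.6
    response_rate: float = 1.0
    model: str = "independent"
    consensus_noise: float = 0.1
    seed: int = 0
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        if self.n_agencies < 2:
            raise ValueError("need at least 2 agencies")
        if self.model not in ("independent", "consensus"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 <= self.agreement_prob <= 1.0):
            raise ValueError("agreement_prob must lie in [0, 1]")
        if not (0.0 < self.response_rate <= 1.0):
            raise ValueError("response_rate must lie in (0, 1]")
        if not (0.0 <= self.consensus_noise <= 1.0):
            raise ValueError("consensus_noise must lie in [0, 1]")
        p = self.categorical()
        if p.size != self.scale.n_categories:
            raise ValueError(
                f"rating_distribution needs {self.scale.n_categories} entries"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("rating_distribution must be a probability vector")

    def categorical(self) -> np.ndarray:
        if self.rating_distribution is None:
            k = self.scale.n_categories
            return np.full(k, 1.0 / k)
        return np.asarray(self.rating_distribution, dtype=float)


def _uniform_other(rng: np.random.Generator, same_as: np.ndarray, k: int) -> np.ndarray:
    """Draw uniformly from the k-1 categories (0-based) differing from same_as."""
    shift = rng.integers(1, k, size=same_as.shape)
    return (same_as + shift) % k


def generate(config: SyntheticConfig) -> RatingMatrixPair:
    """Generate one rating-matrix pair under the configured model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_agencies
    k = config.scale.n_categories
    p = config.categorical()
    agencies = [f"A{i + 1:02d}" for i in range(n)]
    off = ~np.eye(n, dtype=bool)

    if config.model == "independent":
        expected0 = rng.choice(k, size=(n, n), p=p)  # 0-based categories
        match = rng.random(size=(n, n)) < config.agreement_prob
        perceived0 = np.where(
            match, expected0, _uniform_other(rng, expected0, k)
        )
    else:  # consensus
        latent = rng.choice(k, size=(n, n), p=p)
        latent = np.triu(latent, 1) + np.triu(latent, 1).T  # one value per dyad
        def noisy(base: np.ndarray) -> np.ndarray:
            keep = rng.random(size=base.shape) < 1.0 - config.consensus_noise
            return np.where(keep, base, _uniform_other(rng, base, k))
        perceived0 = noisy(latent)
        expected0 = noisy(latent)

    perceived = np.where(off, (perceived0 + config.scale.low).astype(float), np.nan)
    expected = np.where(off, (expected0 + config.scale.low).astype(float), np.nan)

    responded = rng.random(n) < config.response_rate
    perceived[:, ~responded] = np.nan
    expected[:, ~responded] = np.nan
    return RatingMatrixPair(agencies, perceived, expected, config.scale)


def _perceived_marginal(p: np.ndarray, theta: float) -> np.ndarray:
    """Marginal category distribution of a perceived cell, independent model."""
    k = p.size
    return theta * p + (1.0 - theta) * (1.0 - p) / (k - 1)


def _channel(k: int, noise: float) -> np.ndarray:
    """Noisy-channel matrix C[t, a] = P(observed a | latent t)."""
    c = np.full((k, k), noise / (k - 1))
    np.fill_diagonal(c, 1.0 - noise)
    return c


def expected_scores(config: SyntheticConfig, tolerance: int = 0) -> dict[str, float]:
    """Exact expected agreement per perspective, by lattice enumeration.

    Returns a mapping ``{"P1": ..., "P2": ..., "P3": ..., "P4": ...}`` of the
    probability that a random rating pair of each perspective agrees (within
    the ordinal *tolerance*, default exact equality).
    """
    p = config.categorical()
    k = p.size
    agree = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) <= tolerance

    if config.model == "independent":
        theta = config.agreement_prob
        # Same-cell joint: P(E=e) * P(P=a | E=e).
        cond = np.full((k, k), (1.0 - theta) / (k - 1))
        np.fill_diagonal(cond, theta)
        joint_same = p[:, None] * cond
        same = float(np.sum(joint_same * agree))
        # Cross-cell: independent perceived and expected cells.
        q = _perceived_marginal(p, theta)
        cross = float(np.sum(np.outer(q, p) * agree))
        return {"P1": same, "P2": cross, "P3": cross, "P4": same}

    # Consensus: both members of every perspective pair are independent noisy
    # readings of the same dyad latent, so all perspectives coincide.
    c = _channel(k, config.consensus_noise)
    per_latent = np.einsum("ta,tb,ab->t", c, c, agree.astype(float))
    val = float(np.dot(p, per_latent))
    return {"P1": val, "P2": val, "P3": val, "P4": val}
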