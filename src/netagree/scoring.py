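"""Agency-level integration scores and closed-form global estimators.

Integration of an agency X is measured as percentage agreement between
perceived and expected involvement ratings, from four perspectives built out
of X's self-ratings (its matrix column) and its group-ratings (its row).
For every partner j != X the following rating pairs are formed:

========  =============================  ==========================
P1        group-perceived vs group-expected   (perceived[X,j], expected[X,j])
P2        self-perceived vs group-expected    (perceived[j,X], expected[X,j])
P3        group-perceived vs self-expected    (perceived[X,j], expected[j,X])
P4        self-perceived vs self-expected     (perceived[j,X], expected[j,X])
========  =============================  ==========================

A pair is *valid* when both members are observed and *agreed* when the two
ratings are exactly equal (an ordinal tolerance can be configured but
defaults to strict equality).  The score is agreed/valid; pairs with a
missing member are excluded from both counts (pairwise deletion), so
non-respondents — who have no self-ratings — get P1 only.

The global score of the network, for one perspective, is summarised either
by the plain mean of the defined agency scores with a normal-approximation
confidence interval, or by an inverse-variance weighted mean in which more
precisely estimated agency scores count more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import RatingMatrixPair

__all__ = [
    "PERSPECTIVES",
    "AgencyScore",
    "AgencyScoreSet",
    "GlobalEstimate",
    "agency_scores",
    "score_table",
    "defined_scores",
    "global_mean",
    "global_weighted",
]

PERSPECTIVES = ("P1", "P2", "P3", "P4")


@dataclass(frozen=True)
class AgencyScore:
    """Agreement count for one agency under one perspective."""

    perspective: str
    agreed: int
    valid: int

    def __post_init__(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if not (0 <= self.agreed <= self.valid):
            raise ValueError(
                f"agreed={self.agreed} must lie in [0, valid={self.valid}]"
            )
        if self.valid < 1:
            raise ValueError("a defined score needs at least one valid pair")

    @property
    def score(self) -> float:
        """Agreement fraction in [0, 1]."""
        return self.agreed / self.valid


@dataclass(frozen=True)
class AgencyScoreSet:
    """P1..P4 for one agency; perspectives without valid pairs are None."""

    agency: str
    p1: AgencyScore | None
    p2: AgencyScore | None
    p3: AgencyScore | None
    p4: AgencyScore | None

    def get(self, perspective: str) -> AgencyScore | None:
        return {"P1": self.p1, "P2": self.p2, "P3": self.p3, "P4": self.p4}[
            perspective
        ]


@dataclass(frozen=True)
class GlobalEstimate:
    """Network-level summary of one perspective by one estimation method."""

    perspective: str
    method: str  # mean | weighted | boot_standard | boot_balanced | boot_bayes
    estimate: float
    interval_low: float
    interval_high: float
    interval_kind: str  # normal | bca | credible
    n_agencies_used: int
    replicates: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.interval_low > self.interval_high:
            raise ValueError("interval_low must not exceed interval_high")


def _perspective_pairs(
    pair: RatingMatrixPair, x: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    row_p = pair.perceived[x, :]
    row_e = pair.expected[x, :]
    col_p = pair.perceived[:, x]
    col_e = pair.expected[:, x]
    keep = np.arange(pair.n) != x
    return {
        "P1": (row_p[keep], row_e[keep]),
        "P2": (col_p[keep], row_e[keep]),
        "P3": (row_p[keep], col_e[keep]),
        "P4": (col_p[keep], col_e[keep]),
    }


def agency_scores(
    pair: RatingMatrixPair, agency: str, tolerance: int = 0
) -> AgencyScoreSet:
    """Compute the four perspective scores for one agency.

    Parameters
    ----------
    tolerance
        Maximum absolute ordinal difference still counted as agreement;
        0 (default) demands exact equality.
    """
    x = pair.index(agency)
    out: dict[str, AgencyScore | None] = {}
    for persp, (a, b) in _perspective_pairs(pair, x).items():
        both = np.isfinite(a) & np.isfinite(b)
        valid = int(both.sum())
        if valid == 0:
            out[persp] = None
            continue
        agreed = int((np.abs(a[both] - b[both]) <= tolerance).sum())
        out[persp] = AgencyScore(persp, agreed, valid)
    return AgencyScoreSet(agency, out["P1"], out["P2"], out["P3"], out["P4"])


def score_table(pair: RatingMatrixPair, tolerance: int = 0) -> list[AgencyScoreSet]:
    """Per-agency score sets, in the pair's agency order."""
    return [agency_scores(pair, a, tolerance) for a in pair.agencies]


def defined_scores(
    score_sets: Iterable[AgencyScoreSet], perspective: str
) -> list[AgencyScore]:
    """The defined scores of one perspective, preserving agency order.

    Because non-respondents have no self-ratings, P2–P4 lists automatically
    contain respondents only; P1 may include every agency.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    return [s for ss in score_sets if (s := ss.get(perspective)) is not None]


def _z(confidence: float) -> float:
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    return float(stats.norm.ppf((1.0 + confidence) / 2.0))


def _as_fractions(scores: Sequence[AgencyScore | float]) -> np.ndarray:
    return np.array(
        [s.score if isinstance(s, AgencyScore) else float(s) for s in scores]
    )


def global_mean(
    scores: Sequence[AgencyScore | float],
    confidence: float = 0.95,
    perspective: str = "P1",
) -> GlobalEstimate:
    """Plain-average global score with a normal-approximation interval.

    estimate = mean(s_i); interval = estimate +/- z * sd / sqrt(n), clipped
    to the unit interval.  Requires at least two defined scores so that the
    interval exists.
    """
    vals = _as_fractions(scores)
    n = vals.size
    if n < 2:
        raise ValueError("global mean needs >= 2 defined agency scores")
    est = float(vals.mean())
    half = _z(confidence) * float(vals.std(ddof=1)) / np.sqrt(n)
    return GlobalEstimate(
        perspective=perspective,
        method="mean",
        estimate=est,
        interval_low=max(0.0, est - half),
        interval_high=min(1.0, est + half),
        interval_kind="normal",
        n_agencies_used=n,
    )


def global_weighted(
    scores: Sequence[AgencyScore],
    confidence: float = 0.95,
    perspective: str = "P1",
) -> GlobalEstimate:
    """Inverse-variance weighted global score.

    Each agency score s_i = agreed_i / valid_i is a proportion; its variance
    is estimated as ptilde_i (1 - ptilde_i) / valid_i with the shrunken
    ptilde_i = (agreed_i + 0.5) / (valid_i + 1) so that boundary scores
    (0 or 1) do not receive infinite weight.  Weights w_i = 1 / var_i give

        estimate = sum(w_i s_i) / sum(w_i),
        interval = estimate +/- z * sqrt(1 / sum(w_i)),

    clipped to [0, 1].  The raw scores themselves are never shrunk.
    """
    if len(scores) < 2:
        raise ValueError("weighted global needs >= 2 defined agency scores")
    if any(not isinstance(s, AgencyScore) for s in scores):
        raise TypeError("global_weighted needs AgencyScore objects (counts)")
    s = np.array([sc.score for sc in scores])
    agreed = np.array([sc.agreed for sc in scores], dtype=float)
    valid = np.array([sc.valid for sc in scores], dtype=float)
    ptilde = (agreed + 0.5) / (valid + 1.0)
    var = ptilde * (1.0 - ptilde) / valid
    w = 1.0 / var
    est = float(np.sum(w * s) / np.sum(w))
    half = _z(confidence) * float(np.sqrt(1.0 / np.sum(w)))
    return GlobalEstimate(
        perspective=perspective,
        method="weighted",
        estimate=min(1.0, max(0.0, est)),
        interval_low=max(0.0, est - half),
        interval_high=min(1.0, est + half),
        interval_kind="normal",
        n_agencies_used=len(scores),
    )
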