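"""Presentation artifacts: score tables, global-score tables, and figures.

Tables follow the survey-report conventions: agency scores as whole
percentages (half rounded away from zero), globals with their intervals.
Figures are strict views of already-computed scores — a spider (radar) plot
of one agency's four perspective scores, and an integration-area diagram in
which agencies are sorted by score and drawn as equal-width bars, so the
filled fraction of the unit plotting box equals the network's mean score
and the blank remainder depicts the integration gap.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .model import RatingMatrixPair, round_half_away_from_zero
from .resampling import (
    BootstrapResult,
    bootstrap_balanced,
    bootstrap_bayes,
    bootstrap_standard,
)
from .scoring import (
    PERSPECTIVES,
    AgencyScoreSet,
    GlobalEstimate,
    defined_scores,
    global_mean,
    global_weighted,
    score_table,
)

__all__ = [
    "scores_frame",
    "global_table",
    "globals_frame",
    "spider_plot",
    "integration_area_plot",
    "area_profile",
]

GLOBAL_METHODS = ("mean", "weighted", "boot_standard", "boot_balanced", "boot_bayes")


def _pct(fraction: float | None) -> float | None:
    if fraction is None:
        return None
    return float(round_half_away_from_zero(100.0 * fraction))


def scores_frame(score_sets: Sequence[AgencyScoreSet]) -> pd.DataFrame:
    """Score table: one row per agency, whole-percent scores, pair counts."""
    rows = []
    for ss in score_sets:
        row: dict[str, object] = {"agency": ss.agency}
        respondent = any(ss.get(p) is not None for p in ("P2", "P3", "P4"))
        for p in PERSPECTIVES:
            sc = ss.get(p)
            row[f"{p.lower()}_pct"] = _pct(sc.score if sc else None)
            row[f"{p.lower()}_valid"] = sc.valid if sc else 0
        row["respondent"] = respondent
        rows.append(row)
    return pd.DataFrame(rows)


def global_table(
    pair: RatingMatrixPair,
    perspectives: Sequence[str] = PERSPECTIVES,
    methods: Sequence[str] = GLOBAL_METHODS,
    B: int = 40_000,
    confidence: float = 0.95,
    seed: int = 0,
    tolerance: int = 0,
) -> list[GlobalEstimate]:
    """Global estimates for each requested perspective x method.

    Bootstrap seeds are derived deterministically from *seed* so that each
    (perspective, method) combination gets an independent but reproducible
    stream.
    """
    sets = score_table(pair, tolerance)
    out: list[GlobalEstimate] = []
    combos = [(p, m) for p in perspectives for m in methods]
    children = np.random.SeedSequence(seed).spawn(len(combos))
    sub = {c: int(ch.generate_state(1)[0] % (2**31)) for c, ch in zip(combos, children)}
    for p in perspectives:
        scores = defined_scores(sets, p)
        for m in methods:
            if m == "mean":
                out.append(global_mean(scores, confidence, p))
            elif m == "weighted":
                out.append(global_weighted(scores, confidence, p))
            elif m in ("boot_standard", "boot_balanced", "boot_bayes"):
                fn = {
                    "boot_standard": bootstrap_standard,
                    "boot_balanced": bootstrap_balanced,
                    "boot_bayes": bootstrap_bayes,
                }[m]
                res: BootstrapResult = fn(
                    [s.score for s in scores], B, confidence, sub[(p, m)]
                )
                out.append(
                    GlobalEstimate(
                        perspective=p,
                        method=m,
                        estimate=res.point,
                        interval_low=res.interval[0],
                        interval_high=res.interval[1],
                        interval_kind=res.interval_kind,
                        n_agencies_used=len(scores),
                        replicates=B,
                        seed=res.seed,
                    )
                )
            else:
                raise ValueError(f"unknown method {m!r}")
    return out


def globals_frame(estimates: Iterable[GlobalEstimate]) -> pd.DataFrame:
    """Global-score table with one-decimal percentages."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "perspective": e.perspective,
                "method": e.method,
                "estimate_pct": round(100.0 * e.estimate, 1),
                "ci_low_pct": round(100.0 * e.interval_low, 1),
                "ci_high_pct": round(100.0 * e.interval_high, 1),
                "interval_kind": e.interval_kind,
                "n": e.n_agencies_used,
                "replicates": e.replicates,
                "seed": e.seed,
            }
        )
    return pd.DataFrame(rows)


def spider_plot(score_set: AgencyScoreSet, out_path: str | Path) -> Path:
    """Radar chart of one agency's P1–P4 scores on a 0–100% radial axis.

    Undefined perspectives are left as gaps in the polygon; an agency at
    100% everywhere draws the complete diamond.  Raises ValueError when no
    perspective is defined.
    """
    values = {p: score_set.get(p) for p in PERSPECTIVES}
    if all(v is None for v in values.values()):
        raise ValueError(f"agency {score_set.agency!r} has no defined score")

    angles = np.pi / 2 - 2 * np.pi * np.arange(4) / 4  # P1 top, clockwise
    fig = Figure(figsize=(4, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(projection="polar")
    ax.set_ylim(0, 100)
    ax.set_xticks(angles)
    ax.set_xticklabels(PERSPECTIVES)
    ax.set_yticks([25, 50, 75, 100])

    defined = [values[p] is not None for p in PERSPECTIVES]
    if all(defined):
        theta = np.append(angles, angles[0])
        r = np.array([100.0 * values[p].score for p in PERSPECTIVES])
        r = np.append(r, r[0])
        ax.plot(theta, r, "o-", color="tab:blue")
        ax.fill(theta, r, alpha=0.25, color="tab:blue")
    else:
        th = [a for a, d in zip(angles, defined) if d]
        r = [100.0 * values[p].score for p, d in zip(PERSPECTIVES, defined) if d]
        ax.plot(th, r, "o", color="tab:blue")
    ax.set_title(f"Agency {score_set.agency}")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    return out_path


def area_profile(scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Step-profile coordinates of the integration-area diagram.

    Agencies are sorted by descending score and each occupies a horizontal
    segment of width 1/n on the unit interval; the returned (x, y) arrays
    trace the top of the filled region.  The area under the profile equals
    the arithmetic mean of the scores exactly.
    """
    s = np.sort(np.asarray(scores, dtype=float))[::-1]
    if s.size == 0:
        raise ValueError("need at least one defined score")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must be fractions in [0, 1]")
    n = s.size
    edges = np.arange(n + 1) / n
    x = np.repeat(edges, 2)[1:-1]
    y = np.repeat(s, 2)
    return x, y


def integration_area_plot(
    scores: Sequence[float], out_path: str | Path, perspective: str | None = None
) -> Path:
    """Integration-area diagram for one perspective.

    The shaded area inside the unit box is the network's mean integration
    score; the blank remainder is the integration gap.
    """
    x, y = area_profile(scores)
    mean = float(np.mean(scores))
    fig = Figure(figsize=(5, 3.2))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot()
    ax.fill_between(x, 0.0, y, color="tab:blue", alpha=0.6, label="integration")
    ax.fill_between(x, y, 1.0, color="0.9", label="gap")
    ax.plot(x, y, color="tab:blue")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("agencies (sorted, equal widths)")
    ax.set_ylabel("integration score")
    title = f"Global integration = {100 * mean:.1f}%"
    if perspective:
        title = f"{perspective}: {title}"
    ax.set_title(title)
    ax.legend(loc="upper right", frameon=False)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    return out_path
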