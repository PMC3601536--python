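"""Independent brute-force oracles kept deliberately separate from the
library implementation: plain-Python loops and textbook formulas only."""

from __future__ import annotations

import math

from scipy.stats import norm


def brute_force_scores(pair, agency: str, tolerance: int = 0):
    """Materialise every (perspective, partner) rating pair and count
    equalities with explicit loops.  Returns {perspective: (agreed, valid)}."""
    x = list(pair.agencies).index(agency)
    out = {}
    for persp in ("P1", "P2", "P3", "P4"):
        agreed = valid = 0
        for j in range(len(pair.agencies)):
            if j == x:
                continue
            if persp == "P1":
                a, b = pair.perceived[x][j], pair.expected[x][j]
            elif persp == "P2":
                a, b = pair.perceived[j][x], pair.expected[x][j]
            elif persp == "P3":
                a, b = pair.perceived[x][j], pair.expected[j][x]
            else:
                a, b = pair.perceived[j][x], pair.expected[j][x]
            if math.isnan(a) or math.isnan(b):
                continue
            valid += 1
            if abs(a - b) <= tolerance:
                agreed += 1
        out[persp] = (agreed, valid)
    return out


def _quantile_linear(sorted_vals, alpha: float) -> float:
    """np.quantile's default 'linear' rule, re-implemented by hand."""
    m = len(sorted_vals)
    h = (m - 1) * alpha
    lo = math.floor(h)
    hi = min(lo + 1, m - 1)
    frac = h - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def bca_oracle(scores, replicate_means, sample_mean, confidence):
    """Textbook BCa endpoints computed with scalar arithmetic only."""
    reps = sorted(float(r) for r in replicate_means)
    B = len(reps)
    prop = sum(1 for r in reps if r < sample_mean) / B
    z0 = norm.ppf(prop)
    n = len(scores)
    total = sum(scores)
    loo = [(total - s) / (n - 1) for s in scores]
    mbar = sum(loo) / n
    num = sum((mbar - m) ** 3 for m in loo)
    den = 6.0 * (sum((mbar - m) ** 2 for m in loo)) ** 1.5
    a = num / den if den > 0 else 0.0
    ends = []
    for zk in (norm.ppf((1 - confidence) / 2), norm.ppf((1 + confidence) / 2)):
        t = z0 + zk
        alpha = norm.cdf(z0 + t / (1 - a * t))
        ends.append(_quantile_linear(reps, float(alpha)))
    return (min(ends), max(ends))


def cross_agreement_oracle(p, theta: float, tolerance: int = 0) -> float:
    """Expected cross-cell agreement (P2/P3) for the independent generator,
    by explicit scalar enumeration over the category lattice."""
    k = len(p)
    q = [theta * p[i] + (1 - theta) * (1 - p[i]) / (k - 1) for i in range(k)]
    total = 0.0
    for a in range(k):
        for b in range(k):
            if abs(a - b) <= tolerance:
                total += q[a] * p[b]
    return total
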