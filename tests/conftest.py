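"""Shared fixtures: the illustrative 4-agency network and random builders."""

from __future__ import annotations

import numpy as np
import pytest

from netagree import RatingMatrixPair, RatingScale


def build_illustrative_pair() -> RatingMatrixPair:
    """The published organising example, completed to a full 4-agency network.

    Agency A's four rating vectors are fixed by the illustration:
    self-perceived (1,1,1), self-expected (1,2,3) down column A;
    group-perceived (2,3,4), group-expected (1,1,1) along row A.
    The B/C/D dyads are filled with constant 3s; they do not enter
    Agency A's scores.
    """
    n = 4
    p = np.full((n, n), np.nan)
    e = np.full((n, n), np.nan)
    p[1:, 0] = [1, 1, 1]
    e[1:, 0] = [1, 2, 3]
    p[0, 1:] = [2, 3, 4]
    e[0, 1:] = [1, 1, 1]
    for i in range(1, n):
        for j in range(1, n):
            if i != j:
                p[i, j] = 3
                e[i, j] = 3
    return RatingMatrixPair(["A", "B", "C", "D"], p, e)


def random_pair(
    rng: np.random.Generator,
    n: int,
    missing_prob: float = 0.0,
    nonrespondent_prob: float = 0.0,
    scale: RatingScale | None = None,
) -> RatingMatrixPair:
    """A random valid network with optional item- and unit-non-response."""
    scale = scale or RatingScale()
    cats = np.arange(scale.low, scale.high + 1)
    p = rng.choice(cats, size=(n, n)).astype(float)
    e = rng.choice(cats, size=(n, n)).astype(float)
    np.fill_diagonal(p, np.nan)
    np.fill_diagonal(e, np.nan)
    if missing_prob > 0:
        p[rng.random((n, n)) < missing_prob] = np.nan
        e[rng.random((n, n)) < missing_prob] = np.nan
    for j in range(n):
        if rng.random() < nonrespondent_prob:
            p[:, j] = np.nan
            e[:, j] = np.nan
    agencies = [f"G{i}" for i in range(n)]
    return RatingMatrixPair(agencies, p, e, scale)


def build_group_agreement_network(n_raters: int, n_agree: int) -> RatingMatrixPair:
    """One target agency X plus *n_raters* raters, exactly *n_agree* of whom
    give X identical group-perceived and group-expected ratings; the others
    are offset by one category.  Rater-rater dyads are filled in so the
    matrices look like a complete survey."""
    n = n_raters + 1
    p = np.full((n, n), np.nan)
    e = np.full((n, n), np.nan)
    for j in range(1, n):
        e[0, j] = 3.0
        p[0, j] = 3.0 if j <= n_agree else 4.0
    for i in range(1, n):
        for j in range(1, n):
            if i != j:
                p[i, j] = 2.0
                e[i, j] = 2.0
    agencies = ["X"] + [f"R{j}" for j in range(1, n)]
    return RatingMatrixPair(agencies, p, e)


@pytest.fixture
def illustrative_pair() -> RatingMatrixPair:
    return build_illustrative_pair()
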