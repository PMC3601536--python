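"""Core data model for paired perceived/expected involvement ratings.

An inter-agency service network of ``n`` agencies is surveyed on an ordinal
involvement scale (by default 5 points, 1..5).  Each responding agency rates
its *perceived* (current) and *expected* (optimal) level of involvement with
every other agency.  The responses are organised as two square matrices with
a fixed orientation:

* column ``j`` holds agency ``j``'s own ratings about every other agency
  (its *self-ratings*);
* row ``i`` holds every other agency's ratings about agency ``i``
  (its *group-ratings*);
* hence cell ``[i, j]`` (``i != j``) is agency ``j``'s rating of its
  involvement with agency ``i``.

The diagonal is undefined (agencies do not rate themselves) and is stored as
NaN.  A *non-respondent* returned no questionnaire: its column is entirely
missing in both matrices, while its row may still be populated by the
agencies that did respond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RatingScale",
    "RatingMatrixPair",
    "RepresentativeRecord",
    "round_half_away_from_zero",
]


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer with .5 ties going away from zero.

    Python's built-in ``round`` uses banker's rounding (3.5 -> 4 but
    2.5 -> 2); survey-averaging conventions normally resolve a tied mean
    upward in magnitude, so 2.5 -> 3 here.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class RatingScale:
    """Inclusive integer bounds of the ordinal involvement scale.

    The canonical instrument is a 5-point scale coded 1..5, but the bounds
    are configurable so that 0..4 or wider codings validate correctly.
    """

    low: int = 1
    high: int = 5

    def __post_init__(self) -> None:
        if not (isinstance(self.low, int) and isinstance(self.high, int)):
            raise TypeError("scale bounds must be integers")
        if self.high <= self.low:
            raise ValueError(f"scale high ({self.high}) must exceed low ({self.low})")

    @property
    def n_categories(self) -> int:
        return self.high - self.low + 1

    @property
    def categories(self) -> range:
        return range(self.low, self.high + 1)

    def check_value(self, value: float, *, what: str = "rating") -> None:
        """Raise ValueError unless *value* is an integer within the bounds."""
        if not np.isfinite(value) or float(value) != int(value):
            raise ValueError(f"{what} {value!r} is not an integer")
        if not (self.low <= int(value) <= self.high):
            raise ValueError(
                f"{what} {int(value)} outside scale [{self.low}, {self.high}]"
            )


@dataclass(frozen=True)
class RepresentativeRecord:
    """One representative's raw rating of a directed agency pair.

    ``respondent`` is the agency answering the questionnaire; ``partner`` the
    agency being rated.  Raw values may be non-integer only in the sense that
    they are later averaged; each individual response must sit on the scale.
    """

    respondent: str
    partner: str
    representative: str
    perceived_raw: float
    expected_raw: float

    def __post_init__(self) -> None:
        if self.respondent == self.partner:
            raise ValueError(
                f"agency {self.respondent!r} cannot rate its own involvement"
            )


class RatingMatrixPair:
    """Paired square perceived/expected rating matrices with missingness.

    Parameters
    ----------
    agencies
        Ordered unique agency identifiers (opaque strings).
    perceived, expected
        ``n x n`` float arrays; NaN marks a missing cell, the diagonal must
        be entirely NaN.  Cell ``[i, j]`` is agency ``j``'s rating about its
        involvement with agency ``i``.
    scale
        Ordinal bounds used to validate every finite cell.
    """

    def __init__(
        self,
        agencies: Sequence[str],
        perceived: np.ndarray,
        expected: np.ndarray,
        scale: RatingScale | None = None,
    ) -> None:
        self.agencies: tuple[str, ...] = tuple(str(a) for a in agencies)
        self.scale = scale if scale is not None else RatingScale()
        self.perceived = np.asarray(perceived, dtype=float).copy()
        self.expected = np.asarray(expected, dtype=float).copy()
        self._validate()
        self.perceived.flags.writeable = False
        self.expected.flags.writeable = False

    def _validate(self) -> None:
        n = len(self.agencies)
        if n < 2:
            raise ValueError("a network needs at least 2 agencies")
        if len(set(self.agencies)) != n:
            raise ValueError("agency identifiers must be unique")
        for name, mat in (("perceived", self.perceived), ("expected", self.expected)):
            if mat.shape != (n, n):
                raise ValueError(
                    f"{name} matrix has shape {mat.shape}, expected {(n, n)}"
                )
            diag = np.diagonal(mat)
            if np.isfinite(diag).any():
                raise ValueError(
                    f"{name} matrix has a non-missing diagonal (self-rating) cell"
                )
            finite = mat[np.isfinite(mat)]
            for v in finite:
                self.scale.check_value(v, what=f"{name} cell value")

    # -- derived structure -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.agencies)

    @property
    def respondent_flags(self) -> np.ndarray:
        """Boolean per agency: did its column return any rating at all?"""
        return np.isfinite(self.perceived).any(axis=0) | np.isfinite(
            self.expected
        ).any(axis=0)

    def index(self, agency: str) -> int:
        try:
            return self.agencies.index(agency)
        except ValueError:
            raise KeyError(f"unknown agency {agency!r}") from None

    def is_respondent(self, agency: str) -> bool:
        return bool(self.respondent_flags[self.index(agency)])

    # -- convenience -------------------------------------------------------

    def relabel(self, mapping: dict[str, str]) -> "RatingMatrixPair":
        """Return a copy with agency identifiers renamed (order preserved)."""
        new = [mapping.get(a, a) for a in self.agencies]
        return RatingMatrixPair(new, self.perceived, self.expected, self.scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingMatrixPair):
            return NotImplemented
        return (
            self.agencies == other.agencies
            and self.scale == other.scale
            and _nan_equal(self.perceived, other.perceived)
            and _nan_equal(self.expected, other.expected)
        )

    def __repr__(self) -> str:
        nresp = int(self.respondent_flags.sum())
        return (
            f"RatingMatrixPair(n={self.n}, respondents={nresp}, "
            f"scale=[{self.scale.low}..{self.scale.high}])"
        )


def _nan_equal(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and bool(
        np.all((a == b) | (np.isnan(a) & np.isnan(b)))
    )


def empty_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two all-missing n x n rating matrices (helper for builders)."""
    return np.full((n, n), np.nan), np.full((n, n), np.nan)
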