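"""Reading and writing rating matrices.

Two plain-text formats are supported:

* **wide CSV** — one file per matrix.  Header row and first column carry the
  agency identifiers, the body carries integer ratings, the empty string
  marks a missing cell, and the diagonal is empty.  A pair of such files
  (perceived + expected) round-trips exactly through
  :func:`read_matrix_pair` / :func:`write_matrix_pair`.
* **long CSV** — one row per representative per directed pair, with columns
  ``respondent, partner, representative, perceived, expected``.  Agencies
  with several representatives are collapsed by averaging their ratings and
  rounding to the nearest integer (ties away from zero by default).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    RatingMatrixPair,
    RatingScale,
    RepresentativeRecord,
    round_half_away_from_zero,
)

__all__ = [
    "read_matrix_pair",
    "write_matrix_pair",
    "read_long_records",
    "collapse_representatives",
]


def _read_wide(path: str | Path, scale: RatingScale, what: str):
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    labels = [str(c) for c in df.columns]
    rows = [str(r) for r in df.index]
    if rows != labels:
        raise ValueError(
            f"{what} file {path}: row labels do not match column labels "
            f"(rows {rows[:5]}..., columns {labels[:5]}...)"
        )
    n = len(labels)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            raw = df.iat[i, j].strip()
            if i == j:
                if raw != "":
                    raise ValueError(
                        f"{what} file {path}: non-empty diagonal cell for "
                        f"agency {labels[i]!r} (malformed export)"
                    )
                continue
            if raw == "":
                continue
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(
                    f"{what} file {path}: cell [{labels[i]!r}, {labels[j]!r}] "
                    f"value {raw!r} is not an integer"
                ) from None
            scale.check_value(value, what=f"{what} cell [{labels[i]!r}, {labels[j]!r}]")
            mat[i, j] = value
    return labels, mat


def read_matrix_pair(
    perceived_path: str | Path,
    expected_path: str | Path,
    scale: RatingScale | None = None,
) -> RatingMatrixPair:
    """Read a perceived/expected wide-CSV pair into a validated matrix pair.

    Agency order is taken from the perceived file; the expected file must
    list the identical agencies in the identical order.
    """
    scale = scale if scale is not None else RatingScale()
    p_labels, perceived = _read_wide(perceived_path, scale, "perceived")
    e_labels, expected = _read_wide(expected_path, scale, "expected")
    if p_labels != e_labels:
        raise ValueError(
            "perceived and expected files disagree on agencies: "
            f"{sorted(set(p_labels) ^ set(e_labels)) or 'same set, different order'}"
        )
    return RatingMatrixPair(p_labels, perceived, expected, scale)


def write_matrix_pair(
    pair: RatingMatrixPair,
    perceived_path: str | Path,
    expected_path: str | Path,
) -> None:
    """Write the pair as two wide CSVs that read back bit-identically."""
    for mat, path in ((pair.perceived, perceived_path), (pair.expected, expected_path)):
        cells = [
            ["" if not np.isfinite(v) else str(int(v)) for v in row] for row in mat
        ]
        df = pd.DataFrame(cells, index=list(pair.agencies), columns=list(pair.agencies))
        df.to_csv(path)


def read_long_records(path: str | Path) -> list[RepresentativeRecord]:
    """Read per-representative ratings from a long CSV."""
    records: list[RepresentativeRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"respondent", "partner", "representative", "perceived", "expected"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ValueError(f"long CSV {path} missing columns: {sorted(missing)}")
        for row in reader:
            records.append(
                RepresentativeRecord(
                    respondent=row["respondent"].strip(),
                    partner=row["partner"].strip(),
                    representative=row["representative"].strip(),
                    perceived_raw=float(row["perceived"]),
                    expected_raw=float(row["expected"]),
                )
            )
    return records


def collapse_representatives(
    records: Iterable[RepresentativeRecord],
    agencies: Sequence[str] | None = None,
    scale: RatingScale | None = None,
    ties: str = "away_from_zero",
) -> RatingMatrixPair:
    """Average multiple representatives per agency into one matrix pair.

    For every directed (respondent, partner) pair the arithmetic mean of all
    representatives' raw ratings is rounded to the nearest integer and stored
    at cell ``[partner, respondent]`` (the respondent's column).  Pairs with
    no record stay missing.  The result is independent of record order.

    Parameters
    ----------
    agencies
        Closed agency universe; defaults to the sorted set of identifiers
        appearing in the records.
    ties
        ``"away_from_zero"`` (default: 3.5 -> 4) or ``"to_even"`` (3.5 -> 4,
        2.5 -> 2, the IEEE convention).
    """
    scale = scale if scale is not None else RatingScale()
    if ties == "away_from_zero":
        rounder = round_half_away_from_zero
    elif ties == "to_even":
        rounder = lambda x: int(round(x))  # noqa: E731 - builtin banker's rounding
    else:
        raise ValueError(f"unknown tie rule {ties!r}")

    records = list(records)
    for rec in records:
        for name, v in (("perceived", rec.perceived_raw), ("expected", rec.expected_raw)):
            if not (scale.low <= v <= scale.high):
                raise ValueError(
                    f"{name} raw value {v} for ({rec.respondent!r} -> "
                    f"{rec.partner!r}) outside [{scale.low}, {scale.high}]"
                )

    if agencies is None:
        agencies = sorted(
            {r.respondent for r in records} | {r.partner for r in records}
        )
    idx = {a: k for k, a in enumerate(agencies)}
    for rec in records:
        for a in (rec.respondent, rec.partner):
            if a not in idx:
                raise ValueError(f"record references unknown agency {a!r}")

    n = len(agencies)
    perceived = np.full((n, n), np.nan)
    expected = np.full((n, n), np.nan)
    groups: dict[tuple[str, str], list[RepresentativeRecord]] = {}
    for rec in records:
        groups.setdefault((rec.respondent, rec.partner), []).append(rec)
    for (resp, partner), recs in groups.items():
        j, i = idx[resp], idx[partner]
        perceived[i, j] = rounder(float(np.mean([r.perceived_raw for r in recs])))
        expected[i, j] = rounder(float(np.mean([r.expected_raw for r in recs])))
    return RatingMatrixPair(agencies, perceived, expected, scale)
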