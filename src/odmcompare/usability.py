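"""System Usability Scale (SUS) scoring.

SUS is a ten-question instrument rated 1-5; odd-numbered (positively
phrased) questions contribute ``rating - 1``, even-numbered (negatively
phrased) questions contribute ``5 - rating``, and the sum is scaled by 2.5
to a 0-100 score.  Scores are therefore always multiples of 2.5.
"""

from __future__ import annotations

import csv
from dataclasses import astuple, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SusResponse",
    "sus_score",
    "sus_summary",
    "read_sus_csv",
    "EVALUATION_RESPONSES",
]


@dataclass(frozen=True)
class SusResponse:
    """One participant's ten SUS ratings, each an integer in 1..5."""

    r1: int
    r2: int
    r3: int
    r4: int
    r5: int
    r6: int
    r7: int
    r8: int
    r9: int
    r10: int

    def __post_init__(self) -> None:
        for i, r in enumerate(astuple(self), start=1):
            if not isinstance(r, int) or isinstance(r, bool) or not 1 <= r <= 5:
                raise ValueError(f"SUS rating r{i}={r!r} must be an integer in 1..5")

    @classmethod
    def from_sequence(cls, ratings: Sequence[int]) -> "SusResponse":
        if len(ratings) != 10:
            raise ValueError(f"expected 10 ratings, got {len(ratings)}")
        return cls(*ratings)


def sus_score(resp: SusResponse | Sequence[int]) -> float:
    """SUS score in [0, 100]: 2.5 * (sum_odd(r-1) + sum_even(5-r))."""
    if not isinstance(resp, SusResponse):
        resp = SusResponse.from_sequence(resp)
    ratings = astuple(resp)
    odd = sum(r - 1 for r in ratings[0::2])
    even = sum(5 - r for r in ratings[1::2])
    return 2.5 * (odd + even)


def sus_summary(responses: Iterable[SusResponse | Sequence[int]]) -> dict:
    """Per-response scores with mean (half-up, 1 decimal), min and max.

    The unrounded mean is exposed as ``mean_raw``.  Raises on an empty list.
    """
    scores = [sus_score(r) for r in responses]
    if not scores:
        raise ValueError("sus_summary requires at least one response")
    mean_raw = sum(scores) / len(scores)
    mean = float(Decimal(str(mean_raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return {
        "scores": scores,
        "n": len(scores),
        "mean": mean,
        "mean_raw": mean_raw,
        "min": min(scores),
        "max": max(scores),
    }


def read_sus_csv(path: str | Path) -> list[SusResponse]:
    """Read responses from a CSV with ten rating columns per row.

    A header row is skipped if its cells are not all integers."""
    out: list[SusResponse] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            cells = [c.strip() for c in row if c.strip()]
            if not cells:
                continue
            try:
                ratings = [int(c) for c in cells[:10]]
            except ValueError:
                if not out:  # tolerate a header line
                    continue
                raise
            out.append(SusResponse.from_sequence(ratings))
    return out


#: Raw ratings from a 12-participant usability evaluation of a
#: form-comparison tool (final evaluation round); used as a worked example.
EVALUATION_RESPONSES: tuple[SusResponse, ...] = tuple(
    SusResponse.from_sequence(row)
    for row in (
        (4, 2, 4, 1, 5, 1, 5, 1, 4, 2),
        (3, 1, 5, 1, 4, 1, 4, 1, 3, 2),
        (4, 1, 5, 1, 5, 1, 5, 1, 5, 1),
        (5, 3, 4, 2, 4, 1, 4, 2, 4, 1),
        (3, 3, 4, 2, 3, 2, 4, 2, 3, 2),
        (2, 1, 5, 1, 4, 2, 5, 2, 3, 1),
        (4, 2, 5, 2, 4, 1, 5, 1, 5, 1),
        (2, 3, 3, 3, 2, 4, 3, 4, 4, 4),
        (2, 3, 4, 2, 3, 3, 2, 3, 1, 3),
        (4, 1, 4, 3, 5, 1, 4, 2, 3, 1),
        (3, 2, 5, 2, 4, 2, 4, 1, 3, 2),
        (2, 2, 4, 1, 2, 2, 3, 2, 4, 1),
    )
)
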