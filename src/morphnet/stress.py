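"""Life-event questionnaire scoring and stress-group assignment.

The questionnaire has 39 items; each experienced event is rated on a
desirability scale from -2 (very negative) to +2 (very positive).  An item
can also be marked not-experienced, which contributes nothing (it is absent,
not zero).  The negative-event count and the summed negative ratings place
each subject into a Low- or High-stress stratum; scores outside both windows
are Unclassified and excluded from group analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "N_ITEMS",
    "ALLOWED_RATINGS",
    "LOW",
    "HIGH",
    "UNCLASSIFIED",
    "LEQResponse",
    "StressScore",
    "score_leq",
    "assign_group",
    "score_cohort",
    "leq_columns",
]

N_ITEMS = 39
ALLOWED_RATINGS = frozenset({-2, -1, 0, 1, 2})

LOW = "Low"
HIGH = "High"
UNCLASSIFIED = "Unclassified"

# group windows: (min NLE count, max NLE count, min total, max total)
_LOW_WINDOW = (0, 5, -5, 0)
_HIGH_WINDOW = (6, N_ITEMS, -20, -11)


@dataclass(frozen=True)
class LEQResponse:
    """One subject's 39 item ratings; ``None`` marks a not-experienced event."""

    items: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} items, got {len(self.items)}")
        for i, v in enumerate(self.items):
            if v is not None and v not in ALLOWED_RATINGS:
                raise ValueError(f"item {i + 1}: rating {v!r} not in {sorted(ALLOWED_RATINGS)}")

    @classmethod
    def from_iterable(cls, items: Iterable) -> "LEQResponse":
        clean: list[Optional[int]] = []
        for v in items:
            if v is None or pd.isna(v):
                clean.append(None)
            else:
                clean.append(int(v))
        return cls(tuple(clean))


@dataclass(frozen=True)
class StressScore:
    n_nle: int
    negative_total: int
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_nle < 0:
            raise ValueError("n_nle must be >= 0")
        if self.negative_total > 0:
            raise ValueError("negative_total must be <= 0")
        if not self.n_nle <= -self.negative_total <= 2 * self.n_nle:
            raise ValueError(
                f"inconsistent score: {self.n_nle} NLEs cannot total {self.negative_total}"
            )


def score_leq(resp: LEQResponse) -> StressScore:
    """Count and sum the negatively rated events; other items contribute nothing."""
    if not isinstance(resp, LEQResponse):
        resp = LEQResponse.from_iterable(resp)
    neg = [v for v in resp.items if v is not None and v < 0]
    return StressScore(n_nle=len(neg), negative_total=sum(neg))


def assign_group(score: StressScore) -> str:
    """Low / High / Unclassified from the NLE count and negative total."""
    lo_n, hi_n, lo_t, hi_t = _LOW_WINDOW
    if lo_n <= score.n_nle <= hi_n and lo_t <= score.negative_total <= hi_t:
        return LOW
    lo_n, hi_n, lo_t, hi_t = _HIGH_WINDOW
    if lo_n <= score.n_nle <= hi_n and lo_t <= score.negative_total <= hi_t:
        return HIGH
    return UNCLASSIFIED


def leq_columns() -> list[str]:
    """Cohort CSV column names holding the 39 item ratings."""
    return [f"leq_item_{i:02d}" for i in range(1, N_ITEMS + 1)]


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a cohort table.

    Adds (or overwrites) ``n_nle``, ``leq_negative_total`` and
    ``stress_group``.  Item columns follow :func:`leq_columns`; empty cells
    mean not-experienced.
    """
    cols = leq_columns()
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks LEQ item columns: {missing[:3]}...")
    out = cohort.copy()
    n_nle, totals, groups = [], [], []
    for _, row in cohort[cols].iterrows():
        score = score_leq(LEQResponse.from_iterable(row.tolist()))
        score = replace(score, group=assign_group(score))
        n_nle.append(score.n_nle)
        totals.append(score.negative_total)
        groups.append(score.group)
    out["n_nle"] = n_nle
    out["leq_negative_total"] = totals
    out["stress_group"] = groups
    return out
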