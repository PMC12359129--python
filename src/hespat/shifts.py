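"""Temporal and regional comparison of weights, ranks, and tiers.

Sign conventions (they deliberately point in opposite temporal
directions, matching how such shifts are conventionally reported):

* weight shift  = later weight - earlier weight (a positive value means
  the indicator gained discriminating power over time);
* rank / tier shift = earlier - later (a positive value means the
  country *improved*, since smaller ranks are better).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import EntropyResult
from .matrix import DecisionMatrix

__all__ = [
    "ShiftTable",
    "weight_shift",
    "rank_shift",
    "shift_summary",
    "cluster_profile",
    "regional_weight_comparison",
]


@dataclass(frozen=True)
class ShiftTable:
    """Per-entity deltas between two assessment periods."""

    entities: tuple[str, ...]
    value_a: np.ndarray
    value_b: np.ndarray
    shift: np.ndarray
    convention: str             # human-readable sign convention

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity": self.entities,
                "value_a": self.value_a,
                "value_b": self.value_b,
                "shift": self.shift,
            }
        )


def _as_series(values, names=None) -> pd.Series:
    if isinstance(values, pd.Series):
        return values.astype(float)
    values = np.asarray(values, dtype=float)
    if names is None:
        raise ValueError("entity names required for plain arrays")
    return pd.Series(values, index=list(names))


def weight_shift(
    weights_a,
    weights_b,
    indicators: Sequence[str] | None = None,
) -> ShiftTable:
    """Indicator-weight change, later minus earlier.

    Accepts pandas Series (aligned by indicator name) or plain arrays
    plus an ``indicators`` list.  Both vectors must cover the same
    indicator set.  Shifts are computed from unrounded weights and sum
    to zero because both vectors are normalized.
    """
    a = _as_series(weights_a, indicators)
    b = _as_series(weights_b, indicators)
    if set(a.index) != set(b.index):
        raise ValueError("indicator sets differ between periods")
    b = b.reindex(a.index)
    return ShiftTable(
        entities=tuple(map(str, a.index)),
        value_a=a.to_numpy(),
        value_b=b.to_numpy(),
        shift=(b - a).to_numpy(),
        convention="later - earlier (positive = weight gained)",
    )


def rank_shift(
    ranks_a,
    ranks_b,
    countries: Sequence[str] | None = None,
) -> ShiftTable:
    """Rank (or tier) change, earlier minus later; positive = improved."""
    a = _as_series(ranks_a, countries)
    b = _as_series(ranks_b, countries)
    if set(a.index) != set(b.index):
        raise ValueError("country sets differ between periods")
    b = b.reindex(a.index)
    return ShiftTable(
        entities=tuple(map(str, a.index)),
        value_a=a.to_numpy(),
        value_b=b.to_numpy(),
        shift=(a - b).to_numpy(),
        convention="earlier - later (positive = improved)",
    )


def shift_summary(table: ShiftTable) -> pd.DataFrame:
    """Counts and percentages of improved / unchanged / declined.

    Partition is by the sign of the shift; percentages of the total are
    rounded to 2 decimals.
    """
    shift = np.asarray(table.shift, dtype=float)
    m = len(shift)
    counts = {
        "improved": int((shift > 0).sum()),
        "unchanged": int((shift == 0).sum()),
        "declined": int((shift < 0).sum()),
    }
    return pd.DataFrame(
        {
            "outcome": list(counts),
            "count": list(counts.values()),
            "percent": [round(100.0 * c / m, 2) for c in counts.values()],
        }
    )


def cluster_profile(
    matrix: DecisionMatrix,
    tiers: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """Per-tier arithmetic mean of every indicator column.

    Works for pillar-level and sub-indicator matrices alike; every
    country in the matrix must have a tier.  Rows are tiers (ascending,
    1 = best), columns the matrix indicators.
    """
    tiers = pd.Series(dict(tiers)) if not isinstance(tiers, pd.Series) else tiers
    missing = [c for c in matrix.countries if c not in tiers.index]
    if missing:
        raise ValueError(f"no tier for countries: {missing}")
    frame = matrix.to_frame()
    frame["tier"] = [int(tiers[c]) for c in matrix.countries]
    profile = frame.groupby("tier").mean().sort_index()
    profile.columns = list(matrix.indicators)
    return profile


def regional_weight_comparison(
    results: Mapping[tuple[str, str], EntropyResult | pd.Series],
) -> pd.DataFrame:
    """Tidy (region, period, indicator, weight) table across runs.

    ``results`` maps (region, period) to an EntropyResult or a weight
    Series.  Indicator sets must agree across entries; rows are aligned
    by indicator *name*, not by position.
    """
    rows = []
    reference: set[str] | None = None
    for (region, period), res in results.items():
        if isinstance(res, EntropyResult):
            series = pd.Series(res.weights, index=list(res.indicators))
        else:
            series = pd.Series(res, dtype=float)
        names = set(series.index)
        if reference is None:
            reference = names
        elif names != reference:
            raise ValueError(
                f"indicator mismatch for ({region}, {period}): "
                f"{sorted(names ^ reference)}"
            )
        for indicator, weight in series.items():
            rows.append(
                {
                    "region": region,
                    "period": period,
                    "indicator": indicator,
                    "weight": float(weight),
                }
            )
    return pd.DataFrame(rows)
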