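"""Decision-matrix container, delimited/workbook I/O, and validation.

A decision matrix holds bounded performance scores for *m* countries
(rows, the alternatives) against *n* indicators (columns, the criteria).
For GHSI-style data the six pillar indicators are scored 0-100.  Every
downstream stage — entropy weighting, CoCoSo ranking, tier clustering —
consumes this type, so row/column order and naming are preserved
end-to-end and never silently permuted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionMatrix",
    "ValidationReport",
    "read_decision_matrix",
    "read_workbook_matrix",
    "validate_matrix",
    "write_table",
]

DEFAULT_BOUNDS = (0.0, 100.0)


@dataclass(frozen=True)
class DecisionMatrix:
    """Countries × indicators score grid with declared score bounds.

    Parameters
    ----------
    countries : ordered unique country identifiers (length m >= 2).
    indicators : ordered unique indicator names (length n >= 1).
    scores : (m, n) array of real scores inside ``bounds``.
    period_label : free-text assessment period, e.g. ``"2019"``.
    bounds : inclusive (low, high) score range; GHSI convention 0-100.
    """

    countries: tuple[str, ...]
    indicators: tuple[str, ...]
    scores: np.ndarray
    period_label: str = ""
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "countries", tuple(map(str, self.countries)))
        object.__setattr__(self, "indicators", tuple(map(str, self.indicators)))
        m, n = self.m, self.n
        if scores.shape != (m, n):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{m} countries x {n} indicators"
            )
        if m < 2:
            raise ValueError("a decision matrix needs at least 2 countries")
        if n < 1:
            raise ValueError("a decision matrix needs at least 1 indicator")
        if len(set(self.countries)) != m:
            raise ValueError("duplicate country names")
        if len(set(self.indicators)) != n:
            raise ValueError("duplicate indicator names")
        if not np.all(np.isfinite(scores)):
            bad = [
                (self.countries[i], self.indicators[j])
                for i, j in zip(*np.where(~np.isfinite(scores)))
            ]
            raise ValueError(f"non-finite scores at {bad}")
        lo, hi = self.bounds
        if np.any(scores < lo) or np.any(scores > hi):
            bad = [
                (self.countries[i], self.indicators[j], scores[i, j])
                for i, j in zip(*np.where((scores < lo) | (scores > hi)))
            ]
            raise ValueError(f"scores outside bounds [{lo}, {hi}]: {bad}")

    @property
    def m(self) -> int:
        return len(self.countries)

    @property
    def n(self) -> int:
        return len(self.indicators)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores.copy(),
            index=pd.Index(self.countries, name="country"),
            columns=list(self.indicators),
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        period_label: str = "",
        bounds: tuple[float, float] = DEFAULT_BOUNDS,
    ) -> "DecisionMatrix":
        return cls(
            countries=tuple(map(str, frame.index)),
            indicators=tuple(map(str, frame.columns)),
            scores=frame.to_numpy(dtype=float),
            period_label=period_label,
            bounds=bounds,
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_matrix`.

    ``ok`` is true iff no issue carries severity ``"error"``.
    """

    issues: list[tuple[str, str, str]] = field(default_factory=list)
    constant_columns: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def add(self, severity: str, location: str, message: str) -> None:
        self.issues.append((severity, location, message))


def _parse_cell(value, country: str, indicator: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"unparseable score at ({country!r}, {indicator!r}): {value!r}"
        ) from None
    if not np.isfinite(out):
        raise ValueError(f"missing score at ({country!r}, {indicator!r})")
    return out


def _frame_to_matrix(
    raw: pd.DataFrame,
    period_label: str,
    bounds: tuple[float, float],
) -> DecisionMatrix:
    countries = [str(c) for c in raw.index]
    indicators = [str(c) for c in raw.columns]
    if len(set(countries)) != len(countries):
        dupes = sorted({c for c in countries if countries.count(c) > 1})
        raise ValueError(f"duplicate country names: {dupes}")
    if len(set(indicators)) != len(indicators):
        dupes = sorted({c for c in indicators if indicators.count(c) > 1})
        raise ValueError(f"duplicate indicator names: {dupes}")
    scores = np.empty(raw.shape, dtype=float)
    for i, country in enumerate(countries):
        for j, indicator in enumerate(indicators):
            scores[i, j] = _parse_cell(raw.iat[i, j], country, indicator)
    return DecisionMatrix(
        countries=tuple(countries),
        indicators=tuple(indicators),
        scores=scores,
        period_label=period_label,
        bounds=bounds,
    )


def read_decision_matrix(
    path: str | Path,
    dialect: Literal["csv", "tsv"] = "csv",
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    period_label: str | None = None,
) -> DecisionMatrix:
    """Read a delimited country × indicator table.

    First row = indicator names, first column = country identifiers,
    remaining cells numeric.  Row/column order is preserved.  Missing or
    unparseable cells, duplicate names, and out-of-bounds scores are hard
    errors naming the offending row/column.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=object, encoding="utf-8")
    label = period_label if period_label is not None else path.stem
    return _frame_to_matrix(raw, label, bounds)


def read_workbook_matrix(
    path: str | Path,
    sheet: str,
    cell_range: str | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    period_label: str | None = None,
) -> DecisionMatrix:
    """Read a country × indicator block from an xlsx sheet.

    ``cell_range`` is an Excel-style range such as ``"A1:G28"`` whose
    first row holds indicator names and first column country names; when
    omitted the whole used range of the sheet is taken.
    """
    from openpyxl.utils import range_boundaries

    path = Path(path)
    if cell_range is None:
        raw = pd.read_excel(path, sheet_name=sheet, index_col=0, dtype=object)
    else:
        min_col, min_row, max_col, max_row = range_boundaries(cell_range)
        raw = pd.read_excel(
            path,
            sheet_name=sheet,
            header=None,
            skiprows=min_row - 1,
            nrows=max_row - min_row + 1,
            usecols=range(min_col - 1, max_col),
            dtype=object,
        )
        raw.columns = [str(v) for v in raw.iloc[0]]
        raw = raw.iloc[1:].set_index(raw.columns[0])
    label = period_label if period_label is not None else sheet
    return _frame_to_matrix(raw, label, bounds)


def validate_matrix(matrix: DecisionMatrix) -> ValidationReport:
    """Report out-of-bounds scores, constant columns, and tiny m.

    Constant columns carry no discriminating information — they receive
    zero entropy weight downstream — and are listed as warnings.  Fewer
    than 3 countries makes the default k=3 tier clustering infeasible.
    """
    report = ValidationReport()
    lo, hi = matrix.bounds
    for i, j in zip(*np.where((matrix.scores < lo) | (matrix.scores > hi))):
        report.add(
            "error",
            f"{matrix.countries[i]}/{matrix.indicators[j]}",
            f"score {matrix.scores[i, j]} outside bounds [{lo}, {hi}]",
        )
    col_range = matrix.scores.max(axis=0) - matrix.scores.min(axis=0)
    for j in np.where(col_range == 0)[0]:
        name = matrix.indicators[j]
        report.constant_columns.append(name)
        report.add("warning", name, "constant column (zero range)")
    if matrix.m < 3:
        report.add(
            "warning",
            "matrix",
            f"only {matrix.m} countries: k=3 tier clustering infeasible",
        )
    return report


def write_table(
    rows: pd.DataFrame | Sequence[dict] | Iterable[Sequence],
    path: str | Path,
    precision: int = 3,
) -> None:
    """Write a tabular result as CSV with a header row.

    Floats are rendered at ``precision`` decimals (default 3, the
    precision used in published GHSI assessment tables).
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("refusing to write an empty table")
    out = frame.reset_index() if frame.index.name is not None else frame
    out.to_csv(
        Path(path),
        index=False,
        float_format=f"%.{precision}f",
        encoding="utf-8",
    )
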