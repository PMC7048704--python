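"""Annualized rate of change (ARC) between survey years and compound-growth
projection of coverage to a target year.

ARC is the geometric per-year growth rate between two coverage observations::

    arc = ((c2 / c1) ** (1 / (t2 - t1)) - 1) * 100

positive when coverage is increasing.  Projection compounds the ARC from a
base observation and clamps the result to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from ._round import round_half_up


class TrendPoint(NamedTuple):
    year: int
    coverage: float


class UndefinedARCError(ValueError):
    """ARC from a zero starting coverage is undefined."""


@dataclass(frozen=True)
class ProjectionSeries:
    """Per-year projected coverage from a base observation and an ARC."""

    indicator: str
    base_year: int
    base_coverage: float
    arc: float  # percent per year
    years: tuple[int, ...]
    values: tuple[float, ...]  # clamped to [0, 100]
    capped: tuple[bool, ...]  # True where clamping was applied

    def value(self, year: int) -> float:
        return self.values[self.years.index(year)]

    @property
    def cap_year(self) -> int | None:
        """First year the 100% cap (or 0% floor) binds, if any."""
        for year, flag in zip(self.years, self.capped):
            if flag:
                return year
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicator,
                "year": self.years,
                "coverage": self.values,
                "capped": self.capped,
            }
        )


def _validate_point(p: TrendPoint) -> None:
    if not 0.0 <= p.coverage <= 100.0:
        raise ValueError(f"coverage outside [0, 100]: {p.coverage}")


def arc(p1: TrendPoint, p2: TrendPoint) -> float:
    """Annualized rate of change (percent/year) between two observations."""
    _validate_point(p1)
    _validate_point(p2)
    if p2.year <= p1.year:
        raise ValueError(f"end year {p2.year} must exceed start year {p1.year}")
    if p1.coverage == 0:
        raise UndefinedARCError("ARC undefined for zero starting coverage")
    span = p2.year - p1.year
    return ((p2.coverage / p1.coverage) ** (1.0 / span) - 1.0) * 100.0


def project(
    base: TrendPoint, arc_pct: float, target_year: int, indicator: str = ""
) -> ProjectionSeries:
    """Compound ``base.coverage`` forward at ``arc_pct`` percent per year.

    Values are clamped to [0, 100]; the clamp year is recorded per year.
    """
    _validate_point(base)
    if target_year < base.year:
        raise ValueError("target year precedes base year")
    years, values, capped = [], [], []
    growth = 1.0 + arc_pct / 100.0
    for year in range(base.year, target_year + 1):
        raw = base.coverage * growth ** (year - base.year)
        clamped = min(100.0, max(0.0, raw))
        years.append(year)
        values.append(clamped)
        capped.append(clamped != raw)
    return ProjectionSeries(
        indicator=indicator,
        base_year=base.year,
        base_coverage=base.coverage,
        arc=arc_pct,
        years=tuple(years),
        values=tuple(values),
        capped=tuple(capped),
    )


def arc_table(
    coverage: pd.DataFrame,
    year1: int,
    year2: int,
    stratum_type: str = "overall",
    stratum: str = "overall",
) -> pd.DataFrame:
    """Per-indicator ARC between two survey years of a tidy coverage table.

    Indicators missing either year (or with zero/NaN start coverage) get a
    missing ARC rather than an error.  ``arc_1dp`` carries presentation
    rounding.
    """
    subset = coverage[
        (coverage["stratum_type"] == stratum_type) & (coverage["stratum"] == stratum)
    ]
    rows = []
    for indicator in subset["indicator"].unique():
        by_year = subset[subset["indicator"] == indicator].set_index("year")["coverage"]
        c1 = by_year.get(year1)
        c2 = by_year.get(year2)
        value = float("nan")
        if c1 is not None and c2 is not None and pd.notna(c1) and pd.notna(c2) and c1 > 0:
            value = arc(TrendPoint(year1, float(c1)), TrendPoint(year2, float(c2)))
        rows.append(
            {
                "indicator": indicator,
                "coverage_start": float(c1) if c1 is not None else float("nan"),
                "coverage_end": float(c2) if c2 is not None else float("nan"),
                "arc": value,
                "arc_1dp": round_half_up(value, 1),
            }
        )
    return pd.DataFrame(rows)
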