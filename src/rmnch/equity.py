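"""Two-stratum equity comparison, coverage/inequity pattern classification
and equiplot-ready records."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._round import round_half_up
from .synthetic import QUINTILES

HIGH_COVERAGE_LOW_INEQUITY = "high coverage & low inequity"
HIGH_COVERAGE_HIGH_INEQUITY = "high coverage & high inequity"
LOW_COVERAGE_LOW_INEQUITY = "low coverage & low inequity"
LOW_COVERAGE_HIGH_INEQUITY = "low coverage & high inequity"

PATTERNS = (
    HIGH_COVERAGE_LOW_INEQUITY,
    HIGH_COVERAGE_HIGH_INEQUITY,
    LOW_COVERAGE_LOW_INEQUITY,
    LOW_COVERAGE_HIGH_INEQUITY,
)


@dataclass(frozen=True)
class Thresholds:
    """Cut-points separating high/low coverage and high/low inequity.

    Defaults: coverage >= 80% counts as high coverage, absolute gap >= 10
    percentage points counts as high inequity.  Both are configuration, not
    constants of the method.
    """

    coverage: float = 80.0
    gap: float = 10.0


@dataclass(frozen=True)
class EquityResult:
    """Coverage comparison between an advantaged and a disadvantaged stratum.

    ``difference`` is advantaged minus disadvantaged in percentage points; a
    negative value means the disadvantaged stratum is ahead.  ``ratio`` is
    advantaged over disadvantaged, NaN when the disadvantaged coverage is 0.
    """

    indicator: str
    advantaged: str
    disadvantaged: str
    coverage_advantaged: float
    coverage_disadvantaged: float
    difference: float
    ratio: float

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)


@dataclass(frozen=True)
class PatternLabel:
    label: str
    thresholds: Thresholds = field(default_factory=Thresholds)


def equity_gap(
    coverage_advantaged: float,
    coverage_disadvantaged: float,
    indicator: str = "",
    advantaged: str = "advantaged",
    disadvantaged: str = "disadvantaged",
) -> EquityResult:
    """Difference (pp) and ratio between two stratum coverages."""
    for value in (coverage_advantaged, coverage_disadvantaged):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"coverage outside [0, 100]: {value}")
    difference = coverage_advantaged - coverage_disadvantaged
    ratio = (
        coverage_advantaged / coverage_disadvantaged
        if coverage_disadvantaged > 0
        else float("nan")
    )
    return EquityResult(
        indicator=indicator,
        advantaged=advantaged,
        disadvantaged=disadvantaged,
        coverage_advantaged=coverage_advantaged,
        coverage_disadvantaged=coverage_disadvantaged,
        difference=difference,
        ratio=ratio,
    )


def classify_pattern(
    overall_coverage: float,
    gap: float,
    thresholds: Thresholds | None = None,
) -> PatternLabel:
    """Place an indicator in one of the four coverage x inequity quadrants.

    Inequity uses the absolute gap, so a stratum-reversed gap still counts
    toward inequity.
    """
    thresholds = thresholds or Thresholds()
    high_coverage = overall_coverage >= thresholds.coverage
    high_inequity = abs(gap) >= thresholds.gap
    if high_coverage and high_inequity:
        label = HIGH_COVERAGE_HIGH_INEQUITY
    elif high_coverage:
        label = HIGH_COVERAGE_LOW_INEQUITY
    elif high_inequity:
        label = LOW_COVERAGE_HIGH_INEQUITY
    else:
        label = LOW_COVERAGE_LOW_INEQUITY
    return PatternLabel(label=label, thresholds=thresholds)


def equity_table(
    coverage: pd.DataFrame,
    stratum_type: str,
    advantaged: str,
    disadvantaged: str,
    year: int,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Equity results for every indicator present in both strata of a tidy
    coverage table; pattern uses the overall coverage when available."""
    rows = []
    subset = coverage[
        (coverage["year"] == year) & (coverage["stratum_type"] == stratum_type)
    ]
    overall = coverage[
        (coverage["year"] == year) & (coverage["stratum_type"] == "overall")
    ]
    for indicator in subset["indicator"].unique():
        adv = subset[
            (subset["indicator"] == indicator) & (subset["stratum"] == advantaged)
        ]["coverage"]
        dis = subset[
            (subset["indicator"] == indicator) & (subset["stratum"] == disadvantaged)
        ]["coverage"]
        if adv.empty or dis.empty or adv.isna().all() or dis.isna().all():
            continue
        result = equity_gap(
            float(adv.iloc[0]),
            float(dis.iloc[0]),
            indicator=indicator,
            advantaged=advantaged,
            disadvantaged=disadvantaged,
        )
        row = {
            "indicator": indicator,
            "advantaged": advantaged,
            "disadvantaged": disadvantaged,
            "coverage_advantaged": result.coverage_advantaged,
            "coverage_disadvantaged": result.coverage_disadvantaged,
            "difference": result.difference,
            "ratio": result.ratio,
            "difference_1dp": round_half_up(result.difference, 1),
            "ratio_1dp": round_half_up(result.ratio, 1),
        }
        ov = overall[overall["indicator"] == indicator]["coverage"]
        if not ov.empty and not ov.isna().all():
            row["pattern"] = classify_pattern(
                float(ov.iloc[0]), result.difference, thresholds
            ).label
        rows.append(row)
    return pd.DataFrame(rows)


def equiplot_data(coverage: pd.DataFrame, year: int) -> list[dict]:
    """One record per indicator with the five ordered quintile coverages and
    the wealthiest-poorest span; incomplete indicators are flagged."""
    subset = coverage[
        (coverage["year"] == year) & (coverage["stratum_type"] == "wealth")
    ]
    records = []
    for indicator in subset["indicator"].unique():
        values = {}
        for q in QUINTILES:
            rows = subset[
                (subset["indicator"] == indicator) & (subset["stratum"] == q)
            ]["coverage"]
            if not rows.empty and not math.isnan(float(rows.iloc[0])):
                values[q] = float(rows.iloc[0])
        complete = len(values) == len(QUINTILES)
        record = {
            "indicator": indicator,
            "year": year,
            "quintiles": [values.get(q) for q in QUINTILES],
            "complete": complete,
            "span": (
                values[QUINTILES[-1]] - values[QUINTILES[0]] if complete else None
            ),
        }
        records.append(record)
    return records
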