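"""Simplified lives-saved engine: cause-specific deaths averted from coverage
scale-up, with a residual-hazard combination so linked interventions cannot
avert the same death twice.

For each cause and year the proportional mortality reduction is

    reduction = 1 - prod_i (1 - Eff_i * AF_i * max(dCov_i, 0))

over the interventions acting on that cause, where ``Eff`` is effectiveness,
``AF`` the affected fraction of cause deaths, and ``dCov`` the coverage change
between the scale-up and baseline trajectories (as a proportion).  An
additive-capped combination is available for sensitivity analysis.  All
parameters are supplied by the scenario; no country database is embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

RESIDUAL = "residual"
ADDITIVE = "additive"


class TrajectoryGapError(ValueError):
    """A coverage trajectory does not cover a simulated year."""


@dataclass(frozen=True)
class Intervention:
    """One intervention with per-cause effect sizes and two coverage paths."""

    name: str
    effectiveness: Mapping[str, float]  # cause -> proportion in [0, 1]
    affected_fraction: Mapping[str, float]  # cause -> proportion in [0, 1]
    baseline_coverage: Mapping[int, float]  # year -> percent
    scaleup_coverage: Mapping[int, float]  # year -> percent

    def __post_init__(self) -> None:
        for label, mapping in (
            ("effectiveness", self.effectiveness),
            ("affected_fraction", self.affected_fraction),
        ):
            for cause, value in mapping.items():
                if not 0.0 <= value <= 1.0:
                    raise ValueError(
                        f"{self.name}: {label}[{cause}] outside [0, 1]: {value}"
                    )

    def coverage_change(self, year: int, allow_decline: bool = False) -> float:
        """(scale-up - baseline)/100 in ``year``, clamped to [-1, 1]; floored
        at 0 unless declines are allowed."""
        for trajectory in (self.baseline_coverage, self.scaleup_coverage):
            if year not in trajectory:
                raise TrajectoryGapError(
                    f"intervention {self.name!r} has no coverage for year {year}"
                )
        delta = (self.scaleup_coverage[year] - self.baseline_coverage[year]) / 100.0
        delta = max(-1.0, min(1.0, delta))
        if not allow_decline:
            delta = max(delta, 0.0)
        return delta


@dataclass(frozen=True)
class OutcomeGroup:
    """An outcome group (e.g. neonatal) with cause-specific baseline rates.

    ``rate_per`` is the rate denominator: 1000 births for child outcomes,
    100000 for maternal.
    """

    name: str
    cause_rates: Mapping[str, float]  # cause -> deaths per rate_per births
    rate_per: float = 1000.0

    def __post_init__(self) -> None:
        for cause, rate in self.cause_rates.items():
            if rate < 0:
                raise ValueError(f"negative rate for cause {cause!r}: {rate}")

    @property
    def total_rate(self) -> float:
        return float(sum(self.cause_rates.values()))


@dataclass(frozen=True)
class LiSTScenario:
    """Demography, cause-specific mortality and interventions for one run."""

    start_year: int
    end_year: int
    births_per_year: float
    groups: tuple[OutcomeGroup, ...]
    interventions: tuple[Intervention, ...]
    birth_growth_rate: float = 0.0  # proportion per year
    combination: str = RESIDUAL
    allow_coverage_decline: bool = False

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year precedes start_year")
        if self.births_per_year < 0:
            raise ValueError("births_per_year must be nonnegative")
        if self.combination not in (RESIDUAL, ADDITIVE):
            raise ValueError(f"unknown combination mode {self.combination!r}")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def births(self, year: int) -> float:
        return self.births_per_year * (1.0 + self.birth_growth_rate) ** (
            year - self.start_year
        )


@dataclass(frozen=True)
class AvertedResult:
    """Per-year, per-group deaths under both scenarios plus derived rates."""

    by_year: pd.DataFrame  # year, group, baseline_deaths, scenario_deaths, averted
    cumulative: Mapping[str, float]  # group -> total averted
    rates: pd.DataFrame  # year, group, baseline_rate, scenario_rate

    @property
    def total_averted(self) -> float:
        return float(sum(self.cumulative.values()))


def baseline_deaths(scenario: LiSTScenario) -> pd.DataFrame:
    """Deaths per year per group per cause with coverage held at baseline."""
    rows = []
    for year in scenario.years:
        births = scenario.births(year)
        for group in scenario.groups:
            for cause, rate in group.cause_rates.items():
                rows.append(
                    {
                        "year": year,
                        "group": group.name,
                        "cause": cause,
                        "deaths": births * rate / group.rate_per,
                    }
                )
    return pd.DataFrame(rows)


def combined_impact(
    interventions: Iterable[Intervention],
    cause: str,
    year: int,
    mode: str = RESIDUAL,
    allow_decline: bool = False,
) -> float:
    """Proportional reduction in cause-specific mortality in one year."""
    impacts = []
    for iv in interventions:
        if cause not in iv.effectiveness:
            continue
        eff = iv.effectiveness[cause]
        af = iv.affected_fraction.get(cause, 1.0)
        delta = iv.coverage_change(year, allow_decline)
        impacts.append(eff * af * delta)
    if not impacts:
        return 0.0
    if mode == ADDITIVE:
        return min(1.0, max(0.0, sum(impacts)))
    survival = 1.0
    for impact in impacts:
        survival *= 1.0 - impact
    return 1.0 - survival


def deaths_averted(scenario: LiSTScenario) -> AvertedResult:
    """Run the engine: averted(y, group) = sum over causes of baseline deaths
    times the combined impact; scenario deaths = baseline - averted."""
    rows = []
    for year in scenario.years:
        births = scenario.births(year)
        for group in scenario.groups:
            baseline_total = 0.0
            averted_total = 0.0
            for cause, rate in group.cause_rates.items():
                deaths = births * rate / group.rate_per
                reduction = combined_impact(
                    scenario.interventions,
                    cause,
                    year,
                    mode=scenario.combination,
                    allow_decline=scenario.allow_coverage_decline,
                )
                baseline_total += deaths
                averted_total += deaths * reduction
            rows.append(
                {
                    "year": year,
                    "group": group.name,
                    "births": births,
                    "baseline_deaths": baseline_total,
                    "scenario_deaths": baseline_total - averted_total,
                    "averted": averted_total,
                }
            )
    by_year = pd.DataFrame(rows)
    cumulative = by_year.groupby("group")["averted"].sum().to_dict()
    rates = by_year.assign(
        baseline_rate=lambda f: f.apply(
            lambda r: r["baseline_deaths"]
            / r["births"]
            * _rate_per(scenario, r["group"]),
            axis=1,
        ),
        scenario_rate=lambda f: f.apply(
            lambda r: r["scenario_deaths"]
            / r["births"]
            * _rate_per(scenario, r["group"]),
            axis=1,
        ),
    )[["year", "group", "baseline_rate", "scenario_rate"]]
    return AvertedResult(by_year=by_year, cumulative=cumulative, rates=rates)


def _rate_per(scenario: LiSTScenario, group_name: str) -> float:
    for group in scenario.groups:
        if group.name == group_name:
            return group.rate_per
    raise KeyError(group_name)


# ---------------------------------------------------------------------------
# configuration loading


def _expand_trajectory(spec: Mapping, years: range) -> dict[int, float]:
    """A trajectory is either an explicit {year: percent} mapping or a
    compact {'base_year', 'base_coverage', 'arc'} compound-growth spec."""
    if "base_year" in spec:
        from .trends import TrendPoint, project

        series = project(
            TrendPoint(int(spec["base_year"]), float(spec["base_coverage"])),
            float(spec.get("arc", 0.0)),
            max(years),
        )
        return {y: series.value(y) for y in years if y >= series.base_year}
    return {int(year): float(value) for year, value in spec.items()}


def scenario_from_dict(data: Mapping) -> LiSTScenario:
    years = range(int(data["start_year"]), int(data["end_year"]) + 1)
    groups = tuple(
        OutcomeGroup(
            name=g["name"],
            cause_rates={str(c): float(r) for c, r in g["cause_rates"].items()},
            rate_per=float(g.get("rate_per", 1000.0)),
        )
        for g in data["groups"]
    )
    interventions = tuple(
        Intervention(
            name=iv["name"],
            effectiveness={str(c): float(v) for c, v in iv["effectiveness"].items()},
            affected_fraction={
                str(c): float(v) for c, v in iv.get("affected_fraction", {}).items()
            },
            baseline_coverage=_expand_trajectory(iv["baseline_coverage"], years),
            scaleup_coverage=_expand_trajectory(iv["scaleup_coverage"], years),
        )
        for iv in data.get("interventions", [])
    )
    return LiSTScenario(
        start_year=int(data["start_year"]),
        end_year=int(data["end_year"]),
        births_per_year=float(data["births_per_year"]),
        birth_growth_rate=float(data.get("birth_growth_rate", 0.0)),
        groups=groups,
        interventions=interventions,
        combination=data.get("combination", RESIDUAL),
        allow_coverage_decline=bool(data.get("allow_coverage_decline", False)),
    )


def scenario_from_yaml(path: str | Path) -> LiSTScenario:
    with open(path) as handle:
        return scenario_from_dict(yaml.safe_load(handle))
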