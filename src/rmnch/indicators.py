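"""RMNCH indicator definitions, weighted coverage estimation and the
Composite Coverage Index (CCI).

The CCI is a weighted mean of eight intervention coverages spanning four
service domains::

    CCI = 1/4 * ( FP + (SBA + ANC)/2 + (2*DPT3 + MSL + BCG)/4 + (ORT + CPNM)/2 )

where FP is family-planning *need satisfied* (not modern contraceptive
prevalence), SBA skilled attendance at birth, ANC antenatal care by a skilled
provider, DPT3/MSL/BCG vaccination coverages, ORT diarrhoea treatment and
CPNM care-seeking for pneumonia, each in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from ._round import round_half_up
from .synthetic import SurveyDataset

Predicate = Callable[[pd.DataFrame], pd.Series]

#: stratifier name -> column carried by SurveyDataset.unit_frame
STRATIFIERS: dict[str, str] = {
    "wealth": "wealth_quintile",
    "residence": "residence",
    "education": "education",
}

CCI_COMPONENTS: tuple[str, ...] = (
    "fp_need_satisfied",
    "sba",
    "anc_skilled",
    "dpt3",
    "msl",
    "bcg",
    "ort",
    "cpnm",
)


class MissingComponentError(KeyError):
    """A CCI component coverage is absent."""


@dataclass(frozen=True)
class IndicatorDefinition:
    """An indicator as numerator/denominator predicates over one unit table."""

    name: str
    table: str  # households | women | births | children
    denominator: Predicate
    numerator: Predicate


def _all(frame: pd.DataFrame) -> pd.Series:
    return pd.Series(True, index=frame.index)


def _col(name: str) -> Predicate:
    return lambda frame: frame[name] == 1


def _vaccine_age(frame: pd.DataFrame) -> pd.Series:
    return frame["age_months"].between(12, 23)


INDICATORS: dict[str, IndicatorDefinition] = {
    d.name: d
    for d in [
        IndicatorDefinition("cpr_modern", "women", _all, _col("modern_fp")),
        IndicatorDefinition("unmet_need", "women", _all, _col("unmet_need")),
        IndicatorDefinition(
            "fp_need_satisfied",
            "women",
            lambda f: (f["modern_fp"] == 1) | (f["unmet_need"] == 1),
            _col("modern_fp"),
        ),
        IndicatorDefinition("anc_skilled", "births", _all, _col("anc_skilled")),
        IndicatorDefinition("td2plus", "births", _all, _col("td2plus")),
        IndicatorDefinition("sba", "births", _all, _col("sba")),
        IndicatorDefinition("bcg", "children", _vaccine_age, _col("bcg")),
        IndicatorDefinition("dpt3", "children", _vaccine_age, _col("dpt3")),
        IndicatorDefinition("msl", "children", _vaccine_age, _col("msl")),
        IndicatorDefinition(
            "all_basic",
            "children",
            _vaccine_age,
            lambda f: (f["bcg"] == 1)
            & (f["dpt3"] == 1)
            & (f["msl"] == 1)
            & (f["polio3"] == 1),
        ),
        IndicatorDefinition(
            "ort", "children", lambda f: f["diarrhoea"] == 1, _col("ort")
        ),
        IndicatorDefinition(
            "cpnm", "children", lambda f: f["ari"] == 1, _col("care_sought")
        ),
        IndicatorDefinition(
            "vitamin_a",
            "children",
            lambda f: f["age_months"].between(6, 59),
            _col("vitamin_a"),
        ),
        IndicatorDefinition("improved_water", "households", _all, _col("improved_water")),
    ]
}


@dataclass(frozen=True)
class CoverageEstimate:
    """Weighted coverage of one indicator in one stratum."""

    indicator: str
    year: int
    stratum_type: str
    stratum: str
    coverage: float  # percent; NaN when the denominator is empty
    n_weighted: float
    n_unweighted: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.coverage)


def compute_coverage(
    dataset: SurveyDataset,
    definition: IndicatorDefinition,
    year: int,
    stratifier: str | None = None,
) -> list[CoverageEstimate]:
    """Estimate ``100 * sum(w | numerator) / sum(w | denominator)`` per stratum.

    An empty denominator yields an estimate with NaN coverage rather than a
    silent zero.
    """
    frame = dataset.unit_frame(definition.table)
    denom = definition.denominator(frame).to_numpy(dtype=bool)
    numer = definition.numerator(frame).to_numpy(dtype=bool) & denom
    weights = frame["weight"].to_numpy(dtype=float)

    if stratifier is None:
        groups: list[tuple[str, str, np.ndarray]] = [
            ("overall", "overall", np.ones(len(frame), dtype=bool))
        ]
    else:
        column = STRATIFIERS[stratifier]
        if column not in frame.columns:
            raise KeyError(
                f"stratifier {stratifier!r} unavailable for table {definition.table!r}"
            )
        values = frame[column].to_numpy()
        groups = [
            (stratifier, str(level), values == level)
            for level in pd.unique(frame[column])
        ]

    estimates = []
    for stratum_type, stratum, mask in groups:
        d = denom & mask
        n_w = float(weights[d].sum())
        n_u = int(d.sum())
        if n_u == 0:
            coverage = float("nan")
        else:
            coverage = 100.0 * float(weights[numer & mask].sum()) / n_w
        estimates.append(
            CoverageEstimate(
                indicator=definition.name,
                year=year,
                stratum_type=stratum_type,
                stratum=stratum,
                coverage=coverage,
                n_weighted=n_w,
                n_unweighted=n_u,
            )
        )
    return estimates


def coverage_table(
    dataset: SurveyDataset,
    year: int,
    stratifiers: Iterable[str | None] = (None,),
    indicators: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tidy coverage table over the indicator registry.

    Columns: indicator, year, stratum_type, stratum, coverage, n_weighted,
    n_unweighted.
    """
    names = list(indicators) if indicators is not None else list(INDICATORS)
    rows = []
    for stratifier in stratifiers:
        for name in names:
            definition = INDICATORS[name]
            if (
                stratifier is not None
                and STRATIFIERS[stratifier]
                not in dataset.unit_frame(definition.table).columns
            ):
                continue  # e.g. maternal education for household indicators
            rows.extend(compute_coverage(dataset, definition, year, stratifier))
    return pd.DataFrame([e.__dict__ for e in rows])


# ---------------------------------------------------------------------------
# Composite Coverage Index


@dataclass(frozen=True)
class CoverageSet:
    """The eight CCI component coverages, percent in [0, 100]."""

    fp: float
    sba: float
    anc: float
    dpt3: float
    msl: float
    bcg: float
    ort: float
    cpnm: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingComponentError(name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"component {name} outside [0, 100]: {value}")


def compute_cci(components: CoverageSet) -> float:
    """Composite Coverage Index, unrounded percent."""
    c = components
    return 0.25 * (
        c.fp
        + (c.sba + c.anc) / 2.0
        + (2.0 * c.dpt3 + c.msl + c.bcg) / 4.0
        + (c.ort + c.cpnm) / 2.0
    )


_COMPONENT_FIELDS = dict(
    zip(("fp", "sba", "anc", "dpt3", "msl", "bcg", "ort", "cpnm"), CCI_COMPONENTS)
)


def coverage_set_from_table(
    table: pd.DataFrame, year: int, stratum_type: str = "overall", stratum: str = "overall"
) -> CoverageSet:
    """Pull the eight CCI components for one year/stratum from a tidy table."""
    subset = table[
        (table["year"] == year)
        & (table["stratum_type"] == stratum_type)
        & (table["stratum"] == stratum)
    ]
    values: dict[str, float] = {}
    for field_name, indicator in _COMPONENT_FIELDS.items():
        rows = subset[subset["indicator"] == indicator]
        if rows.empty or rows["coverage"].isna().all():
            raise MissingComponentError(indicator)
        values[field_name] = float(rows["coverage"].iloc[0])
    return CoverageSet(**values)


def cci_from_table(
    table: pd.DataFrame,
    year: int,
    stratum_type: str = "overall",
    stratum: str = "overall",
) -> float:
    return compute_cci(coverage_set_from_table(table, year, stratum_type, stratum))


def display(value: float, decimals: int = 0) -> float:
    """Presentation rounding (half-up) to printed-table precision."""
    return round_half_up(value, decimals)


def cci_table(table: pd.DataFrame) -> pd.DataFrame:
    """CCI for every (year, stratum_type, stratum) with all eight components."""
    rows = []
    keys = table[["year", "stratum_type", "stratum"]].drop_duplicates()
    for _, key in keys.iterrows():
        try:
            value = cci_from_table(
                table, key["year"], key["stratum_type"], key["stratum"]
            )
        except MissingComponentError:
            continue
        rows.append(
            {
                "year": key["year"],
                "stratum_type": key["stratum_type"],
                "stratum": key["stratum"],
                "cci": value,
            }
        )
    return pd.DataFrame(rows)


def coverage_map(
    table: pd.DataFrame, year: int, stratum_type: str, stratum: str
) -> Mapping[str, float]:
    """indicator -> coverage for one year/stratum slice."""
    subset = table[
        (table["year"] == year)
        & (table["stratum_type"] == stratum_type)
        & (table["stratum"] == stratum)
    ]
    return dict(zip(subset["indicator"], subset["coverage"]))
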