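"""Synthetic DHS-like survey generation and wealth-index construction.

Generates household/women/births/children microdata with known per-quintile
coverage probabilities, so that coverage estimation, equity stratification and
trend analysis can be tested end to end without access-controlled survey data.
Also houses the asset-index (first principal component of standardized asset
indicators) and weighted wealth-quintile machinery, which applies to any
household asset matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

QUINTILES: tuple[str, ...] = ("poorest", "poorer", "middle", "wealthier", "wealthiest")

DEFAULT_ASSETS: tuple[str, ...] = (
    "electricity",
    "radio",
    "television",
    "bicycle",
    "motorcycle",
    "telephone",
    "refrigerator",
    "improved_floor",
)

#: indicators drawn directly per eligible unit; anything absent from a config's
#: coverage_spec falls back to these national-scale probabilities (percent).
DEFAULT_COVERAGE: dict[str, float] = {
    "cpr_modern": 43.0,
    "unmet_need": 24.0,
    "anc_skilled": 86.0,
    "td2plus": 65.0,
    "sba": 63.0,
    "bcg": 98.0,
    "dpt3": 86.0,
    "msl": 90.0,
    "polio3": 88.0,
    "ort": 61.4,
    "cpnm": 84.9,
    "vitamin_a": 83.0,
    "improved_water": 95.0,
}


class ConfigurationError(ValueError):
    """Raised for an invalid survey configuration."""


class DegenerateVarianceError(ValueError):
    """Raised when no asset column carries variance."""


@dataclass(frozen=True)
class SurveyConfig:
    """Parameters controlling a synthetic survey draw.

    ``coverage_spec`` maps indicator name to either a scalar percent (uniform
    across quintiles) or a mapping quintile-label -> percent.
    """

    n_households: int
    year: int
    seed: int
    coverage_spec: Mapping[str, Mapping[str, float] | float] = field(default_factory=dict)
    asset_catalog: Sequence[str] = DEFAULT_ASSETS
    residence_split: float = 0.4
    education_split: float = 0.6
    fertility_spec: float = 0.35
    rural_weight_factor: float = 1.25
    diarrhoea_rate: float = 0.15
    ari_rate: float = 0.12

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        for name, value in (
            ("residence_split", self.residence_split),
            ("education_split", self.education_split),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.fertility_spec < 0:
            raise ConfigurationError("fertility_spec must be nonnegative")
        for indicator, spec in self.coverage_spec.items():
            values = spec.values() if isinstance(spec, Mapping) else [spec]
            for v in values:
                if not 0.0 <= float(v) <= 100.0:
                    raise ConfigurationError(
                        f"coverage for {indicator!r} outside [0, 100]: {v}"
                    )

    def probability(self, indicator: str, quintile: str) -> float:
        """True Bernoulli probability for ``indicator`` in ``quintile``."""
        spec = self.coverage_spec.get(indicator, DEFAULT_COVERAGE.get(indicator, 50.0))
        if isinstance(spec, Mapping):
            spec = spec[quintile]
        return float(spec) / 100.0

    def to_dict(self) -> dict:
        return {
            "n_households": self.n_households,
            "year": self.year,
            "seed": self.seed,
            "coverage_spec": {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in self.coverage_spec.items()
            },
            "asset_catalog": list(self.asset_catalog),
            "residence_split": self.residence_split,
            "education_split": self.education_split,
            "fertility_spec": self.fertility_spec,
            "rural_weight_factor": self.rural_weight_factor,
            "diarrhoea_rate": self.diarrhoea_rate,
            "ari_rate": self.ari_rate,
        }


@dataclass(frozen=True)
class WealthAssignment:
    """Per-household asset-index score and wealth quintile."""

    household_id: np.ndarray
    score: np.ndarray
    quintile: np.ndarray  # labels from QUINTILES

    def share(self, weights: np.ndarray) -> dict[str, float]:
        """Weighted population share of each quintile."""
        total = float(np.sum(weights))
        return {
            q: float(np.sum(weights[self.quintile == q])) / total for q in QUINTILES
        }


@dataclass
class SurveyDataset:
    """Linked microdata tables mimicking a DHS household survey."""

    households: pd.DataFrame
    women: pd.DataFrame
    births: pd.DataFrame
    children: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        hh = set(self.households["household_id"])
        if not set(self.women["household_id"]) <= hh:
            raise ValueError("women reference unknown households")
        wm = set(self.women["woman_id"])
        if not set(self.births["woman_id"]) <= wm:
            raise ValueError("births reference unknown women")
        if not set(self.children["woman_id"]) <= wm:
            raise ValueError("children reference unknown women")
        if (self.households["weight"] <= 0).any():
            raise ValueError("household weights must be strictly positive")

    # -- joins -----------------------------------------------------------
    def unit_frame(self, table: str) -> pd.DataFrame:
        """Unit table joined with household weight, residence, quintile and
        (for births/children) the mother's education."""
        hh_cols = ["household_id", "weight", "residence", "wealth_quintile"]
        if table == "households":
            return self.households.copy()
        women = self.women.merge(self.households[hh_cols], on="household_id")
        if table == "women":
            return women
        mother = women[
            ["woman_id", "weight", "residence", "wealth_quintile", "education"]
        ]
        if table == "births":
            return self.births.merge(mother, on="woman_id")
        if table == "children":
            return self.children.merge(mother, on="woman_id")
        raise KeyError(f"unknown table {table!r}")

    # -- serialization ---------------------------------------------------
    def to_csv(self, directory: str | Path, config: SurveyConfig | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("households", "women", "births", "children"):
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)
        if config is not None:
            sidecar = {"config": config.to_dict(), "seed": config.seed}
            (directory / "survey_meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, directory: str | Path) -> "SurveyDataset":
        directory = Path(directory)
        return cls(
            households=pd.read_csv(directory / "households.csv"),
            women=pd.read_csv(directory / "women.csv"),
            births=pd.read_csv(directory / "births.csv"),
            children=pd.read_csv(directory / "children.csv"),
        )


# ---------------------------------------------------------------------------
# wealth index


def compute_asset_index(assets: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Score each household on the first principal component of its
    standardized asset indicators.

    Zero-variance columns are ignored, the component sign is oriented so a
    higher score means more assets on average, and scores are standardized to
    mean 0, variance 1.
    """
    X = np.asarray(assets, dtype=float)
    if X.ndim != 2:
        raise ValueError("asset matrix must be 2-dimensional")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 households")
    std = X.std(axis=0)
    keep = std > 0
    if not keep.any():
        raise DegenerateVarianceError("all asset columns are constant")
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
    corr = (Z.T @ Z) / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    component = eigvecs[:, -1]
    scores = Z @ component
    # orient: higher score <=> more assets owned
    wealth_proxy = Xk.sum(axis=1)
    if np.cov(scores, wealth_proxy)[0, 1] < 0:
        scores = -scores
    sd = scores.std()
    if sd == 0:
        raise DegenerateVarianceError("asset index has zero variance")
    return (scores - scores.mean()) / sd


def assign_wealth_quintiles(
    scores: np.ndarray,
    weights: np.ndarray,
    household_id: np.ndarray | None = None,
) -> WealthAssignment:
    """Partition households into weighted population quintiles of the score.

    Households are ranked by score (ties broken by stable input order); the
    household whose preceding cumulative weight falls in ``[0.2q, 0.2(q+1))``
    of the total belongs to quintile ``q``.  Each quintile's total weight is
    therefore within one household-weight of 20% of the population.
    """
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if scores.shape != weights.shape:
        raise ValueError("scores and weights must align")
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    if household_id is None:
        household_id = np.arange(scores.size)
    order = np.argsort(scores, kind="stable")
    cum_before = np.concatenate([[0.0], np.cumsum(weights[order])[:-1]])
    total = float(weights.sum())
    bins = np.minimum((5.0 * cum_before / total).astype(int), 4)
    quintile = np.empty(scores.size, dtype=object)
    quintile[order] = np.asarray(QUINTILES, dtype=object)[bins]
    return WealthAssignment(
        household_id=np.asarray(household_id), score=scores, quintile=quintile
    )


# ---------------------------------------------------------------------------
# generation


def _draw(rng: np.random.Generator, p: np.ndarray | float, size: int) -> np.ndarray:
    return (rng.random(size) < p).astype(int)


def generate_survey(config: SurveyConfig) -> SurveyDataset:
    """Draw a full linked survey whose per-quintile indicator probabilities
    equal ``config.coverage_spec``. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    hh_id = np.arange(1, n + 1)

    urban = rng.random(n) < config.residence_split
    residence = np.where(urban, "urban", "rural")
    weight = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    weight = np.where(urban, weight, weight * config.rural_weight_factor)

    # latent wealth drives ground-truth quintiles and the asset gradient;
    # urban households sit higher on the distribution on average
    latent = rng.normal(size=n) + np.where(urban, 0.6, 0.0)
    assignment = assign_wealth_quintiles(latent, weight, hh_id)
    quintile = assignment.quintile
    q_index = np.array([QUINTILES.index(q) for q in quintile])

    assets = {}
    n_assets = len(config.asset_catalog)
    for j, asset in enumerate(config.asset_catalog):
        base = 0.08 + 0.5 * j / max(n_assets - 1, 1)  # vary rarity across catalog
        p = np.clip(base + 0.17 * q_index - 0.25, 0.02, 0.98)
        assets[asset] = _draw(rng, p, n)

    p_water = np.array([config.probability("improved_water", q) for q in quintile])
    households = pd.DataFrame(
        {
            "household_id": hh_id,
            "weight": weight,
            "residence": residence,
            "wealth_quintile": quintile,
            "improved_water": _draw(rng, p_water, n),
            **assets,
        }
    )

    # one ever-married woman of reproductive age per household
    woman_id = hh_id.copy()
    p_edu = np.clip(config.education_split + 0.12 * (q_index - 2), 0.0, 1.0)
    education = np.where(rng.random(n) < p_edu, "educated", "no_education")

    def per_quintile(indicator: str) -> np.ndarray:
        return np.array([config.probability(indicator, q) for q in quintile])

    modern = _draw(rng, per_quintile("cpr_modern"), n)
    # unmet need only among women not using a modern method
    p_unmet = per_quintile("unmet_need")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_unmet_cond = np.where(modern == 0, np.minimum(p_unmet / np.maximum(1e-12, 1 - per_quintile("cpr_modern")), 1.0), 0.0)
    unmet = _draw(rng, p_unmet_cond, n)
    women = pd.DataFrame(
        {
            "woman_id": woman_id,
            "household_id": hh_id,
            "education": education,
            "modern_fp": modern,
            "unmet_need": unmet,
        }
    )

    # births within the 2-year recall window
    n_births = rng.poisson(config.fertility_spec, size=n)
    b_woman = np.repeat(woman_id, n_births)
    b_quint = np.repeat(quintile, n_births)
    nb = b_woman.size
    b_year = config.year - rng.integers(0, 2, size=nb)

    def birth_p(indicator: str) -> np.ndarray:
        return np.array([config.probability(indicator, q) for q in b_quint])

    births = pd.DataFrame(
        {
            "birth_id": np.arange(1, nb + 1),
            "woman_id": b_woman,
            "year": b_year,
            "sba": _draw(rng, birth_p("sba"), nb),
            "anc_skilled": _draw(rng, birth_p("anc_skilled"), nb),
            "td2plus": _draw(rng, birth_p("td2plus"), nb),
        }
    )

    # children under five
    n_children = rng.poisson(config.fertility_spec * 2.5, size=n)
    c_woman = np.repeat(woman_id, n_children)
    c_quint = np.repeat(quintile, n_children)
    nc = c_woman.size
    age = rng.integers(0, 60, size=nc)

    def child_p(indicator: str) -> np.ndarray:
        return np.array([config.probability(indicator, q) for q in c_quint])

    diarrhoea = _draw(rng, config.diarrhoea_rate, nc)
    ari = _draw(rng, config.ari_rate, nc)
    children = pd.DataFrame(
        {
            "child_id": np.arange(1, nc + 1),
            "woman_id": c_woman,
            "age_months": age,
            "bcg": _draw(rng, child_p("bcg"), nc),
            "dpt3": _draw(rng, child_p("dpt3"), nc),
            "msl": _draw(rng, child_p("msl"), nc),
            "polio3": _draw(rng, child_p("polio3"), nc),
            "diarrhoea": diarrhoea,
            "ort": _draw(rng, child_p("ort"), nc) * diarrhoea,
            "ari": ari,
            "care_sought": _draw(rng, child_p("cpnm"), nc) * ari,
            "vitamin_a": _draw(rng, child_p("vitamin_a"), nc),
        }
    )

    return SurveyDataset(
        households=households, women=women, births=births, children=children
    )
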