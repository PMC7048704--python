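"""Coverage-table IO, pipeline orchestration and run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import equity, indicators, lives_saved, trends
from .synthetic import SurveyConfig, generate_survey

logger = logging.getLogger("rmnch")

REQUIRED_COLUMNS = ("indicator", "year", "stratum_type", "stratum", "coverage")
KEY_COLUMNS = ("indicator", "year", "stratum_type", "stratum")


class CoverageTableError(ValueError):
    """Raised for a malformed coverage table, with row context."""


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy coverage CSV.

    Requires columns indicator, year, stratum_type, stratum, coverage;
    coverage values must be in [0, 100] or blank (explicit missing);
    duplicate (indicator, year, stratum_type, stratum) keys are rejected.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CoverageTableError(f"empty coverage table: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CoverageTableError(f"missing required columns: {missing}")
    if table.empty:
        raise CoverageTableError(f"coverage table has no rows: {path}")
    out_of_range = table[
        table["coverage"].notna()
        & ((table["coverage"] < 0) | (table["coverage"] > 100))
    ]
    if not out_of_range.empty:
        row = out_of_range.index[0]
        raise CoverageTableError(
            f"coverage out of [0, 100] at row {row + 2}: "  # +2: header + 0-base
            f"{out_of_range.loc[row, 'coverage']}"
        )
    duplicated = table.duplicated(subset=list(KEY_COLUMNS))
    if duplicated.any():
        row = table.index[duplicated][0]
        raise CoverageTableError(f"duplicate indicator/year/stratum at row {row + 2}")
    table["year"] = table["year"].astype(int)
    return table


def write_coverage_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def bundled_table(name: str) -> pd.DataFrame:
    """Load a coverage table shipped with the package (e.g. 'table1_coverage')."""
    with resources.as_file(
        resources.files("rmnch.data").joinpath(f"{name}.csv")
    ) as path:
        return read_coverage_table(path)


def bundled_path(filename: str) -> Path:
    with resources.as_file(resources.files("rmnch.data").joinpath(filename)) as path:
        return path


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    survey: SurveyConfig | None = None
    coverage_csv: Path | None = None
    year: int = 2016
    stratifiers: Sequence[str] = ("wealth", "residence", "education")
    thresholds: equity.Thresholds = field(default_factory=equity.Thresholds)
    equity_pairs: Sequence[tuple[str, str, str]] = (
        ("residence", "urban", "rural"),
        ("education", "educated", "no_education"),
        ("wealth", "wealthiest", "poorest"),
    )
    arc_years: tuple[int, int] | None = None
    base_year: int = 2016
    target_year: int = 2030
    scenario_path: Path | None = None

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "survey": self.survey.to_dict() if self.survey else None,
            "coverage_csv": str(self.coverage_csv) if self.coverage_csv else None,
            "year": self.year,
            "stratifiers": list(self.stratifiers),
            "thresholds": {
                "coverage": self.thresholds.coverage,
                "gap": self.thresholds.gap,
            },
            "equity_pairs": [list(p) for p in self.equity_pairs],
            "arc_years": list(self.arc_years) if self.arc_years else None,
            "base_year": self.base_year,
            "target_year": self.target_year,
            "scenario_path": str(self.scenario_path) if self.scenario_path else None,
        }


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, *paths: Path) -> None:
        self.stages.setdefault(stage, []).extend(str(p) for p in paths)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                },
                indent=2,
            )
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute generate/load -> coverage -> CCI -> equity -> ARC/project ->
    avert, writing every stage's output under ``config.out_dir``.

    Deterministic: identical config (including seed) produces byte-identical
    CSV outputs.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, config_hash=config_hash, seed=config.seed)

    def run_stage(stage, fn):
        logger.info("stage %s", stage)
        try:
            return fn()
        except Exception as exc:  # abort with stage context
            manifest.record(stage, Path("<failed>"))
            raise StageError(stage, exc) from exc

    # -- load or generate ------------------------------------------------
    if config.coverage_csv is not None:
        coverage = run_stage("load", lambda: read_coverage_table(config.coverage_csv))
        manifest.record("load", Path(config.coverage_csv))
    else:
        survey_cfg = config.survey or SurveyConfig(
            n_households=4000, year=config.year, seed=config.seed
        )
        dataset = run_stage("simulate", lambda: generate_survey(survey_cfg))
        survey_dir = out / "survey"
        dataset.to_csv(survey_dir, survey_cfg)
        manifest.record("simulate", *sorted(survey_dir.glob("*")))

        def estimate():
            strats: list[str | None] = [None, *config.stratifiers]
            return indicators.coverage_table(dataset, config.year, strats)

        coverage = run_stage("coverage", estimate)
        coverage_path = out / "coverage.csv"
        write_coverage_table(coverage, coverage_path)
        manifest.record("coverage", coverage_path)

    # -- CCI ---------------------------------------------------------------
    cci = run_stage("cci", lambda: indicators.cci_table(coverage))
    cci_path = out / "cci.csv"
    cci.to_csv(cci_path, index=False)
    manifest.record("cci", cci_path)

    # -- equity ------------------------------------------------------------
    def equity_stage():
        frames = []
        for stratum_type, advantaged, disadvantaged in config.equity_pairs:
            if stratum_type not in set(coverage["stratum_type"]):
                continue
            frames.append(
                equity.equity_table(
                    coverage,
                    stratum_type,
                    advantaged,
                    disadvantaged,
                    config.year,
                    config.thresholds,
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    equity_df = run_stage("equity", equity_stage)
    equity_path = out / "equity.csv"
    equity_df.to_csv(equity_path, index=False)
    manifest.record("equity", equity_path)
    equiplot_path = out / "equiplot.json"
    equiplot_path.write_text(
        json.dumps(equity.equiplot_data(coverage, config.year), indent=2)
    )
    manifest.record("equity", equiplot_path)

    # -- trends ------------------------------------------------------------
    def trend_stage():
        years = config.arc_years
        if years is None:
            observed = sorted(coverage["year"].unique())
            if len(observed) < 2:
                return None, None
            years = (observed[0], observed[-1])
        arcs = trends.arc_table(coverage, *years)
        projections = []
        base = coverage[
            (coverage["year"] == config.base_year)
            & (coverage["stratum_type"] == "overall")
        ]
        for _, row in arcs.dropna(subset=["arc"]).iterrows():
            base_rows = base[base["indicator"] == row["indicator"]]
            if base_rows.empty or pd.isna(base_rows["coverage"].iloc[0]):
                continue
            series = trends.project(
                trends.TrendPoint(
                    config.base_year, float(base_rows["coverage"].iloc[0])
                ),
                float(row["arc"]),
                config.target_year,
                indicator=row["indicator"],
            )
            projections.append(series.to_frame())
        proj = (
            pd.concat(projections, ignore_index=True) if projections else pd.DataFrame()
        )
        return arcs, proj

    arcs, projections = run_stage("trends", trend_stage)
    if arcs is not None:
        arc_path = out / "arc.csv"
        arcs.to_csv(arc_path, index=False)
        proj_path = out / "projection.csv"
        projections.to_csv(proj_path, index=False)
        manifest.record("trends", arc_path, proj_path)

    # -- lives saved -------------------------------------------------------
    if config.scenario_path is not None:
        def avert_stage():
            scenario = lives_saved.scenario_from_yaml(config.scenario_path)
            return lives_saved.deaths_averted(scenario)

        result = run_stage("avert", avert_stage)
        averted_path = out / "averted.csv"
        result.by_year.to_csv(averted_path, index=False)
        rates_path = out / "mortality_rates.csv"
        result.rates.to_csv(rates_path, index=False)
        summary_path = out / "averted_summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "cumulative": result.cumulative,
                    "total": result.total_averted,
                },
                indent=2,
            )
        )
        manifest.record("avert", averted_path, rates_path, summary_path)

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest
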