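# rmnch

Equity and coverage analysis for reproductive, maternal, newborn and child
health (RMNCH) interventions: survey-weighted coverage estimation from
DHS-style microdata, the Composite Coverage Index (CCI), two-stratum equity
gaps with a four-quadrant coverage/inequity classification, annualized-rate-
of-change (ARC) projection of coverage, and a simplified lives-saved engine
that converts coverage scale-up into deaths averted with a residual-hazard
combination (linked interventions cannot avert the same death twice).

Because real DHS microdata are access-controlled, the package ships a
synthetic survey generator (`rmnch.synthetic`) that produces linked
household/women/births/children tables with known per-wealth-quintile
coverage probabilities, plus the standard asset-index construction (first
principal component of standardized asset indicators) and weighted wealth
quintiles.

## Modules

| module | contents |
| --- | --- |
| `rmnch.synthetic` | `SurveyConfig`, `generate_survey`, `compute_asset_index`, `assign_wealth_quintiles` |
| `rmnch.indicators` | indicator registry, `compute_coverage`, `coverage_table`, `CoverageSet`, `compute_cci` |
| `rmnch.equity` | `equity_gap`, `classify_pattern`, `equity_table`, `equiplot_data` |
| `rmnch.trends` | `arc`, `project`, `arc_table` |
| `rmnch.lives_saved` | `LiSTScenario`, `baseline_deaths`, `combined_impact`, `deaths_averted` |
| `rmnch.io` / `rmnch.cli` | tidy coverage CSV IO, pipeline orchestration, `rmnch` CLI |

Bundled fixtures (`rmnch/data/`): transcriptions of the published national,
residence- and education-stratified coverage tables as tidy CSV, a synthetic
survey configuration and an illustrative lives-saved scenario.

## CLI

```sh
rmnch simulate --config src/rmnch/data/survey_config.yaml --seed 1 --out out/survey
rmnch coverage --survey out/survey --year 2016 --stratifier wealth --out out/coverage.csv
rmnch cci      --coverage out/coverage.csv --out out/cci.csv
rmnch equity   --coverage out/coverage.csv --year 2016 --stratum-type wealth \
               --advantaged wealthiest --disadvantaged poorest --out out/equity.csv
rmnch project  --coverage out/coverage.csv --year1 2001 --year2 2016 \
               --target-year 2030 --out out/projection.csv
rmnch avert    --scenario src/rmnch/data/scenario.yaml --out out/avert
rmnch run      --survey-config src/rmnch/data/survey_config.yaml \
               --scenario src/rmnch/data/scenario.yaml --seed 1 --out out/run
```

All commands log to stderr and write results to files only; `rmnch run`
writes a `manifest.json` listing every stage output, and identical
config + seed reproduce byte-identical CSVs.

## Notes

- The CCI family-planning term is *need satisfied*, not modern
  contraceptive prevalence; this is the only reading that reproduces the
  published composite values.
- The lives-saved engine is a generic re-implementation of the published
  mechanism; it deliberately does not embed any country database, so the
  shipped scenario is illustrative and its totals are not comparable to
  published country estimates.
- Pattern-classification thresholds default to 80% coverage and a
  10-percentage-point absolute gap and are configurable everywhere.
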