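import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmnch import io
from rmnch.lives_saved import (
    ADDITIVE,
    Intervention,
    LiSTScenario,
    OutcomeGroup,
    TrajectoryGapError,
    baseline_deaths,
    combined_impact,
    deaths_averted,
    scenario_from_yaml,
)

YEARS = range(2016, 2021)


def constant(value):
    return {y: value for y in YEARS}


def make_intervention(name="iv", eff=0.5, af=1.0, base=20.0, scale=60.0, cause="c"):
    return Intervention(
        name=name,
        effectiveness={cause: eff},
        affected_fraction={cause: af},
        baseline_coverage=constant(base),
        scaleup_coverage=constant(scale),
    )


def make_scenario(interventions, rate=10.0, births=100000.0, **kwargs):
    return LiSTScenario(
        start_year=2016,
        end_year=2020,
        births_per_year=births,
        groups=(OutcomeGroup(name="g", cause_rates={"c": rate}),),
        interventions=tuple(interventions),
        **kwargs,
    )


class TestBaselineDeaths:
    def test_nmr_arithmetic(self):
        # 100,000 births/yr at 21/1000 -> 2,100 neonatal deaths/yr
        scenario = make_scenario([], rate=21.0)
        deaths = baseline_deaths(scenario)
        assert (deaths["deaths"] == 2100.0).all()

    def test_zero_births(self):
        scenario = make_scenario([], births=0.0)
        assert (baseline_deaths(scenario)["deaths"] == 0.0).all()

    def test_cause_envelope_conserved(self):
        scenario = LiSTScenario(
            start_year=2016,
            end_year=2016,
            births_per_year=100000.0,
            groups=(OutcomeGroup(name="g", cause_rates={"a": 6.0, "b": 4.0}),),
            interventions=(),
        )
        deaths = baseline_deaths(scenario).set_index("cause")["deaths"]
        assert deaths["a"] == 600.0 and deaths["b"] == 400.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            OutcomeGroup(name="g", cause_rates={"c": -1.0})

    def test_birth_growth(self):
        scenario = make_scenario([], births=1000.0, birth_growth_rate=0.02)
        assert scenario.births(2018) == pytest.approx(1000.0 * 1.02**2)


class TestCombinedImpact:
    def test_single_intervention_hand_oracle(self):
        # [DERIVED] 0.5 * 1.0 * 0.4 = 0.20
        iv = make_intervention(eff=0.5, af=1.0, base=20, scale=60)
        assert combined_impact([iv], "c", 2016) == pytest.approx(0.20)

    def test_no_change_no_impact(self):
        iv = make_intervention(base=60, scale=60)
        assert combined_impact([iv], "c", 2016) == 0.0

    def test_residual_hazard_two_interventions(self):
        # [DERIVED] two 0.20 impacts combine to 1 - 0.8^2 = 0.36 < 0.40
        ivs = [make_intervention(name=f"iv{i}") for i in range(2)]
        assert combined_impact(ivs, "c", 2016) == pytest.approx(0.36)

    def test_additive_mode_caps(self):
        ivs = [make_intervention(name=f"iv{i}", eff=0.9, base=0, scale=100) for i in range(3)]
        assert combined_impact(ivs, "c", 2016, mode=ADDITIVE) == 1.0

    def test_exhaustive_product_oracle(self):
        # [DERIVED] residual-hazard product oracle on 2-4 intervention toys
        impacts_grid = [0.0, 0.1, 0.25, 0.5]
        for n in (2, 3, 4):
            for combo in itertools.product(impacts_grid, repeat=n):
                ivs = [
                    make_intervention(name=f"iv{i}", eff=x, af=1.0, base=0, scale=100)
                    for i, x in enumerate(combo)
                ]
                expected = 1.0 - np.prod([1.0 - x for x in combo])
                assert combined_impact(ivs, "c", 2016) == pytest.approx(expected, abs=1e-12)

    def test_never_exceeds_additive_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            impacts = rng.uniform(0, 1, size=rng.integers(2, 5))
            ivs = [
                make_intervention(name=f"iv{i}", eff=x, base=0, scale=100)
                for i, x in enumerate(impacts)
            ]
            combined = combined_impact(ivs, "c", 2016)
            assert combined <= min(1.0, impacts.sum()) + 1e-12
            if (impacts > 0).sum() > 1:
                assert combined < impacts.sum()

    def test_decline_contributes_nothing_by_default(self):
        iv = make_intervention(base=60, scale=40)
        assert combined_impact([iv], "c", 2016) == 0.0

    def test_effectiveness_validation(self):
        with pytest.raises(ValueError):
            make_intervention(eff=1.4)

    def test_trajectory_gap_names_year(self):
        iv = make_intervention()
        with pytest.raises(TrajectoryGapError, match="2035"):
            iv.coverage_change(2035)


class TestDeathsAverted:
    def test_no_scale_up_zero_averted(self):
        scenario = make_scenario([make_intervention(base=60, scale=60)])
        result = deaths_averted(scenario)
        assert (result.by_year["averted"] == 0.0).all()

    def test_closed_form_toy(self):
        # [DERIVED] 1,000 deaths/yr, Eff 0.5, AF 1, dCov 0.4 -> 200/yr, 1,000 total
        scenario = make_scenario([make_intervention(eff=0.5, af=1.0, base=20, scale=60)])
        result = deaths_averted(scenario)
        assert np.allclose(result.by_year["averted"], 200.0)
        assert result.cumulative["g"] == pytest.approx(1000.0)

    def test_conservation(self):
        scenario = make_scenario(
            [make_intervention(eff=0.7, af=0.8, base=30, scale=90)]
        )
        result = deaths_averted(scenario)
        np.testing.assert_allclose(
            result.by_year["scenario_deaths"] + result.by_year["averted"],
            result.by_year["baseline_deaths"],
        )

    def test_bound_random_scenarios(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(1, 4)
            ivs = [
                make_intervention(
                    name=f"iv{i}",
                    eff=rng.uniform(0, 1),
                    af=rng.uniform(0, 1),
                    base=rng.uniform(0, 100),
                    scale=rng.uniform(0, 100),
                )
                for i in range(n)
            ]
            result = deaths_averted(make_scenario(ivs))
            assert (result.by_year["averted"] >= -1e-12).all()
            assert (
                result.by_year["averted"] <= result.by_year["baseline_deaths"] + 1e-9
            ).all()

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_parameter_recovery(self, eff, af, scale):
        # engine output matches the closed form to 1e-10
        scenario = make_scenario([make_intervention(eff=eff, af=af, base=0, scale=scale)])
        result = deaths_averted(scenario)
        expected = 1000.0 * eff * af * scale / 100.0
        assert result.by_year["averted"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_monotonic_in_effectiveness(self):
        low = deaths_averted(make_scenario([make_intervention(eff=0.3)]))
        high = deaths_averted(make_scenario([make_intervention(eff=0.6)]))
        assert high.cumulative["g"] > low.cumulative["g"]

    def test_rates_series(self):
        scenario = make_scenario([make_intervention(eff=0.5, af=1.0, base=20, scale=60)])
        result = deaths_averted(scenario)
        rates = result.rates.set_index("year")
        assert rates.loc[2016, "baseline_rate"] == pytest.approx(10.0)
        assert rates.loc[2016, "scenario_rate"] == pytest.approx(8.0)


class TestScenarioConfig:
    def test_bundled_scenario_loads(self):
        scenario = scenario_from_yaml(io.bundled_path("scenario.yaml"))
        assert scenario.start_year == 2016 and scenario.end_year == 2030
        assert {g.name for g in scenario.groups} == {
            "maternal",
            "stillbirth",
            "neonatal",
            "postneonatal_under5",
        }
        result = deaths_averted(scenario)
        # no aversion in the base year (scale-up equals baseline there),
        # strictly positive afterwards, bounded by baseline deaths throughout
        base_year = result.by_year["year"] == scenario.start_year
        assert (result.by_year.loc[base_year, "averted"] == 0).all()
        assert (result.by_year.loc[~base_year, "averted"] > 0).all()
        assert (result.by_year["averted"] <= result.by_year["baseline_deaths"]).all()

    def test_compact_trajectory_expansion(self):
        scenario = scenario_from_yaml(io.bundled_path("scenario.yaml"))
        sba = next(iv for iv in scenario.interventions if iv.name == "sba")
        assert sba.scaleup_coverage[2016] == pytest.approx(63.0)
        assert sba.scaleup_coverage[2017] == pytest.approx(63 * 1.117)
        assert sba.scaleup_coverage[2030] == 100.0  # capped

    def test_invalid_combination_mode(self):
        with pytest.raises(ValueError):
            make_scenario([], combination="geometric")
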