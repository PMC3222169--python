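"""Scenario costs, ICER quadrants, acceptability curve, benefit-cost ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alccea.economics import (
    DOMINANT,
    DOMINATED,
    RATIO,
    SW_RATIO,
    UNDEFINED,
    EconSettings,
    benefit_cost_ratio,
    ceac,
    icer,
    net_monetary_benefit,
    scenario_cost,
)
from alccea.interventions import (
    Catalog,
    CostSpec,
    EffectSpec,
    InterventionSpec,
    Scenario,
    ScenarioEntry,
)
from alccea.population import PopulationProfile


@pytest.fixture
def toy_setup():
    catalog = Catalog(
        [
            InterventionSpec(
                id="cbt",
                costs={"harmful": CostSpec(2024, 1702, 2550)},
                effects={"harmful": EffectSpec(0.34, 0.12, 0.56)},
            )
        ]
    )
    population = PopulationProfile(
        n_men=800,
        n_women=200,
        band_fractions={
            "men": {"harmful": 1.0},
            "women": {"harmful": 1.0},
        },
    )
    scenario = Scenario(
        name="toy",
        entries=(
            ScenarioEntry(disorder="harmful", intervention="cbt", coverage=0.10),
        ),
    )
    return scenario, population, catalog


class TestScenarioCost:
    def test_product_oracle(self, toy_setup):
        scenario, population, catalog = toy_setup
        # 1000 harmful drinkers * 10% coverage * €2024
        assert scenario_cost(scenario, population, catalog) == pytest.approx(202_400)

    def test_zero_coverage_costs_nothing(self, toy_setup):
        _, population, catalog = toy_setup
        scenario = Scenario(
            name="none",
            entries=(
                ScenarioEntry(disorder="harmful", intervention="cbt", coverage=0.0),
            ),
        )
        assert scenario_cost(scenario, population, catalog) == 0.0

    def test_costs_ignore_adherence(self, toy_setup):
        """Costs accrue to everyone covered, adherent or not."""
        scenario, population, catalog = toy_setup
        half = Scenario(
            name="half",
            entries=(
                ScenarioEntry(
                    disorder="harmful", intervention="cbt",
                    coverage=0.10, adherence=0.1,
                ),
            ),
        )
        assert scenario_cost(half, population, catalog) == pytest.approx(
            scenario_cost(scenario, population, catalog)
        )

    def test_unknown_intervention_resolution_error(self, toy_setup):
        _, population, catalog = toy_setup
        scenario = Scenario(
            name="bad",
            entries=(
                ScenarioEntry(disorder="harmful", intervention="ghost",
                              coverage=0.1),
            ),
        )
        with pytest.raises(KeyError, match="ghost"):
            scenario_cost(scenario, population, catalog)

    def test_drawn_costs_substitute_point_estimates(self, toy_setup):
        scenario, population, catalog = toy_setup
        value = scenario_cost(
            scenario, population, catalog,
            cost_values={("cbt", "harmful"): 1000.0},
        )
        assert value == pytest.approx(100_000)


class TestIcer:
    @pytest.mark.parametrize(
        "dc,de,flag,value",
        [
            (86e6, 5296, RATIO, 16238.670694864048),
            (-68e6, 16, DOMINANT, math.nan),
            (0, 5, DOMINANT, math.nan),
            (-1, 0, DOMINANT, math.nan),
            (68e6, -16, DOMINATED, math.nan),
            (5, 0, DOMINATED, math.nan),
            (0, -5, DOMINATED, math.nan),
            (-10, -2, SW_RATIO, 5.0),
            (0, 0, UNDEFINED, math.nan),
        ],
    )
    def test_quadrants(self, dc, de, flag, value):
        result = icer(dc, de)
        assert result.flag == flag
        if math.isnan(value):
            assert math.isnan(result.value)
        else:
            assert result.value == pytest.approx(value)

    @settings(max_examples=200, deadline=None)
    @given(dc=st.floats(-1e8, 1e8), de=st.floats(-1e4, 1e4))
    def test_classification_is_exhaustive_and_exclusive(self, dc, de):
        result = icer(dc, de)
        assert result.flag in {RATIO, DOMINANT, DOMINATED, SW_RATIO, UNDEFINED}
        # a ratio appears exactly for the two ratio-bearing quadrants (it may
        # overflow to inf for a vanishing effect increment, but never to NaN)
        assert math.isnan(result.value) == (
            result.flag in {DOMINANT, DOMINATED, UNDEFINED}
        )


class TestCeac:
    def test_anchored_at_zero_when_nothing_is_cost_saving(self):
        settings_ = EconSettings(wtp_grid=(0.0,))
        curve = ceac(np.array([10.0, 30.0]), np.array([1.0, 1.0]), settings_)
        assert curve["probability"].iloc[0] == 0.0

    def test_count_oracle(self):
        settings_ = EconSettings(wtp_grid=(20.0,))
        curve = ceac(np.array([10.0, 30.0]), np.array([1.0, 1.0]), settings_)
        assert curve["probability"].iloc[0] == 0.5

    def test_single_draw(self):
        settings_ = EconSettings(wtp_grid=(1000.0,))
        curve = ceac(np.array([10.0]), np.array([1.0]), settings_)
        assert curve["probability"].iloc[0] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ceac(np.array([1.0]), np.array([1.0, 2.0]), EconSettings())

    def test_ties_count_as_not_cost_effective(self):
        # dC = 0 draws keep the curve at 0 when lambda = 0
        settings_ = EconSettings(wtp_grid=(0.0,))
        curve = ceac(np.zeros(4), np.ones(4), settings_)
        assert curve["probability"].iloc[0] == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        dc=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
        de=st.lists(st.floats(0.01, 1e3), min_size=1, max_size=40),
    )
    def test_monotone_and_bounded_for_positive_effects(self, dc, de):
        n = min(len(dc), len(de))
        settings_ = EconSettings(
            wtp_grid=tuple(float(x) for x in range(0, 60_001, 5_000))
        )
        curve = ceac(np.array(dc[:n]), np.array(de[:n]), settings_)
        p = curve["probability"].to_numpy()
        assert np.all((0 <= p) & (p <= 1))
        assert np.all(np.diff(p) >= 0)

    def test_limit_is_fraction_of_positive_effect_draws(self):
        dc = np.array([5.0, 5.0, 5.0, 5.0])
        de = np.array([1.0, 2.0, -1.0, 0.5])
        settings_ = EconSettings(wtp_grid=(1e12,))
        curve = ceac(dc, de, settings_)
        assert curve["probability"].iloc[0] == 0.75


class TestBenefitCostRatio:
    def test_zero_effect(self):
        assert benefit_cost_ratio(0.0, 1e6, 50_000) == 0.0

    @pytest.mark.parametrize(
        "effect,cost,expected",
        [
            (10_319, 319e6, 1.617398119122257),
            (5_022, 233e6, 1.0776824034334764),
        ],
    )
    def test_arithmetic_oracle(self, effect, cost, expected):
        assert benefit_cost_ratio(effect, cost, 50_000) == pytest.approx(expected)

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            benefit_cost_ratio(10, 0.0, 50_000)

    @settings(max_examples=40, deadline=None)
    @given(
        effect=st.floats(0, 1e5),
        cost=st.floats(1.0, 1e9),
        wtp=st.floats(0, 1e5),
        k=st.floats(0.1, 10),
    )
    def test_linear_in_wtp_and_effect(self, effect, cost, wtp, k):
        base = benefit_cost_ratio(effect, cost, wtp)
        assert benefit_cost_ratio(effect, cost, wtp * k) == pytest.approx(base * k)
        assert benefit_cost_ratio(effect * k, cost, wtp) == pytest.approx(base * k)


class TestSettings:
    def test_grid_must_be_sorted(self):
        with pytest.raises(ValueError, match="ascending"):
            EconSettings(wtp_grid=(10.0, 5.0))

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            EconSettings(wtp=-1.0)

    def test_nmb_vectorised(self):
        nmb = net_monetary_benefit(np.array([10.0, 20.0]), np.array([1.0, 1.0]), 15.0)
        assert nmb.tolist() == [5.0, -5.0]
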