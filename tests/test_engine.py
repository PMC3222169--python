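"""Orchestration: deterministic runs, seeded PSA, common random numbers."""

import numpy as np
import pandas as pd
import pytest

from alccea.economics import UNDEFINED
from alccea.engine import PsaSettings, run_deterministic, run_psa
from alccea.interventions import (
    Catalog,
    CostSpec,
    EffectSpec,
    InterventionSpec,
    Scenario,
    ScenarioEntry,
)


def degenerate_catalog(inputs) -> Catalog:
    """The fixture catalog with every distribution collapsed to a point mass."""
    specs = []
    for spec in inputs.catalog:
        costs = {
            d: CostSpec(c.point, c.point, c.point)
            for d, c in spec.costs.items()
        }
        effects = {
            d: EffectSpec(e.d, e.d, e.d, e.intake_reduction)
            for d, e in spec.effects.items()
        }
        specs.append(
            InterventionSpec(id=spec.id, label=spec.label, costs=costs,
                             effects=effects)
        )
    return Catalog(specs)


class TestDeterministic:
    def test_self_comparison_is_all_zero(self, cfg, inputs, disorder_bands):
        base = inputs.scenarios["base_case"]
        result = run_deterministic(
            base, base, inputs.population, inputs.catalog, cfg.burden,
            cfg.econ, inputs.mortality, disorder_bands,
        )
        assert result.delta_c == 0.0
        assert result.delta_e == 0.0
        assert result.icer.flag == UNDEFINED

    def test_adding_ehealth_costs_more_and_averts_more(self, comparison_added):
        assert comparison_added.delta_c > 0
        assert comparison_added.delta_e > 0
        assert comparison_added.icer.flag == "ratio"

    def test_substitution_scenario_saves_money(self, comparison_substitution):
        """Halving face-to-face coverage in favour of cheap eHealth lowers the
        system cost while leaving averted DALYs nearly unchanged."""
        r = comparison_substitution
        assert r.c1 < r.c0
        assert r.icer.flag == "dominant"
        # population health virtually unchanged: within a few percent
        assert abs(r.delta_e) / r.e0 < 0.05

    def test_identity_delta_invariants(self, comparison_added):
        r = comparison_added
        assert r.delta_c == r.c1 - r.c0
        assert r.delta_e == r.e1 - r.e0
        for outcome in (r.base, r.alternative):
            assert outcome.burden.daly == outcome.burden.yld + outcome.burden.yll

    def test_benefit_cost_ratios_improve_under_ehealth(self, comparison_added):
        assert comparison_added.bcr1 > comparison_added.bcr0

    def test_to_dict_round_trip_fields(self, comparison_added):
        d = comparison_added.to_dict()
        assert d["delta_c"] == pytest.approx(d["c1"] - d["c0"])
        assert d["icer_flag"] == "ratio"


class TestPsa:
    def test_seed_determinism(self, cfg, inputs, disorder_bands):
        args = (
            inputs.scenarios["base_case"],
            inputs.scenarios["ehealth_added"],
            inputs.population,
            inputs.catalog,
            cfg.burden,
            cfg.econ,
            inputs.mortality,
            disorder_bands,
        )
        a = run_psa(*args, PsaSettings(n_iterations=40, seed=123))
        b = run_psa(*args, PsaSettings(n_iterations=40, seed=123))
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        assert a.summary == b.summary

    def test_different_seeds_differ(self, cfg, inputs, disorder_bands):
        args = (
            inputs.scenarios["base_case"],
            inputs.scenarios["ehealth_added"],
            inputs.population,
            inputs.catalog,
            cfg.burden,
            cfg.econ,
            inputs.mortality,
            disorder_bands,
        )
        a = run_psa(*args, PsaSettings(n_iterations=10, seed=1))
        b = run_psa(*args, PsaSettings(n_iterations=10, seed=2))
        assert not np.allclose(a.vector("delta_c"), b.vector("delta_c"))

    def test_point_mass_psa_equals_deterministic(self, cfg, inputs, disorder_bands):
        catalog = degenerate_catalog(inputs)
        base = inputs.scenarios["base_case"]
        alt = inputs.scenarios["ehealth_added"]
        det = run_deterministic(
            base, alt, inputs.population, catalog, cfg.burden, cfg.econ,
            inputs.mortality, disorder_bands,
        )
        psa = run_psa(
            base, alt, inputs.population, catalog, cfg.burden, cfg.econ,
            inputs.mortality, disorder_bands,
            PsaSettings(n_iterations=3, seed=9, sample_conversion_factor=False),
        )
        for col, expected in (
            ("c0", det.c0), ("c1", det.c1), ("e0", det.e0), ("e1", det.e1),
            ("delta_c", det.delta_c), ("delta_e", det.delta_e),
        ):
            np.testing.assert_allclose(
                psa.vector(col), expected, rtol=1e-12, atol=1e-9
            )

    def test_shared_interventions_cancel_exactly(self, cfg, inputs, disorder_bands):
        """Common random numbers: comparing a scenario against itself leaves
        every incremental draw at exactly zero."""
        base = inputs.scenarios["base_case"]
        psa = run_psa(
            base, base, inputs.population, inputs.catalog, cfg.burden,
            cfg.econ, inputs.mortality, disorder_bands,
            PsaSettings(n_iterations=25, seed=5),
        )
        assert np.all(psa.vector("delta_c") == 0.0)
        assert np.all(psa.vector("delta_e") == 0.0)

    def test_increment_isolates_the_added_interventions(
        self, cfg, inputs, disorder_bands
    ):
        """With shared draws, (base vs base+extras) has the same increments as
        (nothing vs extras alone)."""
        base = inputs.scenarios["base_case"]
        alt = inputs.scenarios["ehealth_added"]
        base_pairs = {(e.disorder, e.intervention) for e in base.entries}
        extras = Scenario(
            name="extras",
            entries=tuple(
                e for e in alt.entries
                if (e.disorder, e.intervention) not in base_pairs
            ),
        )
        empty = Scenario(name="empty", entries=())
        kwargs = dict(
            population=inputs.population, catalog=inputs.catalog,
            burden_settings=cfg.burden, econ_settings=cfg.econ,
            mortality=inputs.mortality, bands=disorder_bands,
            psa=PsaSettings(n_iterations=20, seed=77),
        )
        full = run_psa(base, alt, **kwargs)
        isolated = run_psa(empty, extras, **kwargs)
        np.testing.assert_allclose(
            full.vector("delta_c"), isolated.vector("delta_c"),
            rtol=1e-12, atol=1e-4,
        )
        np.testing.assert_allclose(
            full.vector("delta_e"), isolated.vector("delta_e"),
            rtol=1e-9, atol=1e-6,
        )

    def test_psa_mean_converges_to_deterministic_effect(
        self, cfg, inputs, disorder_bands, comparison_added
    ):
        psa = run_psa(
            inputs.scenarios["base_case"],
            inputs.scenarios["ehealth_added"],
            inputs.population, inputs.catalog, cfg.burden, cfg.econ,
            inputs.mortality, disorder_bands,
            PsaSettings(n_iterations=500, seed=42),
        )
        de = psa.vector("delta_e")
        mc_se = de.std(ddof=1) / np.sqrt(len(de))
        assert abs(de.mean() - comparison_added.delta_e) < 3 * mc_se

    def test_iteration_bounds(self):
        with pytest.raises(ValueError):
            PsaSettings(n_iterations=0)
        with pytest.raises(ValueError):
            PsaSettings(n_iterations=10_001)


class TestScaling:
    def test_population_doubling_doubles_everything(
        self, cfg, inputs, disorder_bands, comparison_added
    ):
        doubled = inputs.population.scaled(2.0)
        r2 = run_deterministic(
            inputs.scenarios["base_case"], inputs.scenarios["ehealth_added"],
            doubled, inputs.catalog, cfg.burden, cfg.econ,
            inputs.mortality, disorder_bands,
        )
        r1 = comparison_added
        assert r2.c0 == pytest.approx(2 * r1.c0, rel=1e-12)
        assert r2.c1 == pytest.approx(2 * r1.c1, rel=1e-12)
        for attr in ("yld", "yll", "deaths_averted"):
            assert getattr(r2.base.burden, attr) == pytest.approx(
                2 * getattr(r1.base.burden, attr), rel=1e-9
            )
        # ratios are scale-free
        assert r2.icer.value == pytest.approx(r1.icer.value, rel=1e-9)

    def test_psa_scales_linearly_too(self, cfg, inputs, disorder_bands):
        args = lambda pop: (
            inputs.scenarios["base_case"], inputs.scenarios["ehealth_added"],
            pop, inputs.catalog, cfg.burden, cfg.econ,
            inputs.mortality, disorder_bands, PsaSettings(n_iterations=10, seed=3),
        )
        single = run_psa(*args(inputs.population))
        double = run_psa(*args(inputs.population.scaled(2.0)))
        np.testing.assert_allclose(
            double.vector("delta_c"), 2 * single.vector("delta_c"), rtol=1e-12
        )
        np.testing.assert_allclose(
            double.vector("delta_e"), 2 * single.vector("delta_e"), rtol=1e-9
        )
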