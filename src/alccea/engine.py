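"""Run orchestration: deterministic evaluation and probabilistic sensitivity
analysis (PSA) of a base-case versus an alternative health-care scenario.

In deterministic mode every parameter sits at its mean.  In stochastic mode
each iteration draws one per-participant cost (gamma) and one effect size
(normal) per (intervention, disorder) pair, plus optionally the
disability-weight conversion factor, and evaluates *both* scenarios on the
same draws (common random numbers).  Sharing draws means an intervention
offered at equal coverage in both systems contributes identically to both
arms and cancels from every increment, so scenario differences reflect the
health technologies themselves rather than sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .burden import (
    BurdenResult,
    BurdenSettings,
    deaths_averted,
    stratum_yll_averted,
    yld_averted,
)
from .economics import EconSettings, Icer, benefit_cost_ratio, icer, scenario_cost
from .interventions import (
    Catalog,
    Scenario,
    cost_distribution,
    effect_distribution,
    sample_cost,
    sample_effect,
)
from .population import (
    DOSE_RESPONSE,
    GENDERS,
    MortalityCoefficients,
    MortalityTable,
    PopulationProfile,
    stratify,
)

MAX_PSA_ITERATIONS = 10_000


@dataclass(frozen=True)
class PsaSettings:
    """Monte-Carlo settings: iteration count (500 is sufficient in practice,
    10,000 the hard ceiling), the seed, and whether the conversion factor is
    sampled alongside costs and effects."""

    n_iterations: int = 500
    seed: int = 0
    sample_conversion_factor: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.n_iterations <= MAX_PSA_ITERATIONS):
            raise ValueError(
                f"n_iterations must lie in [1, {MAX_PSA_ITERATIONS}]"
            )


@dataclass(frozen=True)
class ScenarioOutcome:
    """Cost and burden averted of a single scenario."""

    name: str
    cost: float
    burden: BurdenResult

    @property
    def effect(self) -> float:
        """DALYs averted — the scenario's effect measure."""
        return self.burden.daly


@dataclass(frozen=True)
class ComparisonResult:
    """Deterministic comparison of an alternative scenario against a base case."""

    base: ScenarioOutcome
    alternative: ScenarioOutcome
    icer: Icer
    wtp: float
    bcr0: float
    bcr1: float

    @property
    def c0(self) -> float:
        return self.base.cost

    @property
    def c1(self) -> float:
        return self.alternative.cost

    @property
    def e0(self) -> float:
        return self.base.effect

    @property
    def e1(self) -> float:
        return self.alternative.effect

    @property
    def delta_c(self) -> float:
        return self.c1 - self.c0

    @property
    def delta_e(self) -> float:
        return self.e1 - self.e0

    def to_dict(self) -> dict:
        return {
            "base": self.base.name,
            "alternative": self.alternative.name,
            "c0": self.c0,
            "c1": self.c1,
            "e0": self.e0,
            "e1": self.e1,
            "delta_c": self.delta_c,
            "delta_e": self.delta_e,
            "yld0": self.base.burden.yld,
            "yll0": self.base.burden.yll,
            "deaths0": self.base.burden.deaths_averted,
            "yld1": self.alternative.burden.yld,
            "yll1": self.alternative.burden.yll,
            "deaths1": self.alternative.burden.deaths_averted,
            "icer": self.icer.value,
            "icer_flag": self.icer.flag,
            "wtp": self.wtp,
            "bcr0": self.bcr0,
            "bcr1": self.bcr1,
        }


@dataclass(frozen=True)
class PsaResult:
    """Seeded PSA output: per-iteration vectors and summary statistics."""

    iterations: pd.DataFrame  # columns: iteration, c0, c1, e0, e1, delta_c, delta_e, icer, icer_flag
    settings: PsaSettings
    summary: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.iterations)

    def vector(self, name: str) -> np.ndarray:
        return self.iterations[name].to_numpy()


def evaluate_scenario(
    scenario: Scenario,
    population: PopulationProfile,
    catalog: Catalog,
    burden_settings: BurdenSettings,
    mortality: MortalityTable,
    bands: Mapping[str, "object"],
    coeffs: Mapping[str, MortalityCoefficients] | None = None,
    cost_values: dict[tuple[str, str], float] | None = None,
    effect_values: dict[tuple[str, str], float] | None = None,
    conversion_factor: float | None = None,
) -> ScenarioOutcome:
    """Evaluate one scenario: total cost plus burden averted.

    ``bands`` maps band label -> :class:`~alccea.population.AuditBand` (the
    source of per-gender mean intakes); ``cost_values``/``effect_values``
    optionally substitute probabilistic draws keyed by (intervention id,
    disorder).  Intervention contributions are summed per disorder class with
    no interaction terms — the catalog interventions are non-overlapping and
    independent by construction.
    """
    scenario.validate_against(catalog)
    coeffs = dict(DOSE_RESPONSE) if coeffs is None else dict(coeffs)
    strata = stratify(population)
    counts = strata.set_index(["gender", "band"])["count"]
    age_weights = population.age_weights()

    cost = scenario_cost(scenario, population, catalog, cost_values=cost_values)

    yld_total = 0.0
    deaths_total = 0.0
    yll_total = 0.0
    # per-gender deaths accumulate first so the age allocation runs once per
    # gender rather than once per scenario entry
    deaths_by_gender = {g: 0.0 for g in GENDERS}
    for entry in scenario.entries:
        spec = catalog[entry.intervention]
        effect = spec.effect_for(entry.disorder)
        d = (
            effect_values[(entry.intervention, entry.disorder)]
            if effect_values is not None
            else effect.d
        )
        band = bands[entry.disorder]
        for gender in GENDERS:
            count = float(counts.get((gender, entry.disorder), 0.0))
            n_covered = count * entry.coverage
            yld_total += yld_averted(
                n_covered,
                d,
                burden_settings,
                adherence=entry.adherence,
                conversion_factor=conversion_factor,
            )
            deaths = deaths_averted(
                gender,
                count,
                band.mean_intake[gender],
                effect.intake_reduction,
                mortality,
                coeffs[gender],
                burden_settings,
                age_weights,
                coverage=entry.coverage,
                adherence=entry.adherence,
            )
            deaths_by_gender[gender] += deaths
    for gender, deaths in deaths_by_gender.items():
        deaths_total += deaths
        yll_total += stratum_yll_averted(gender, deaths, mortality, age_weights)

    return ScenarioOutcome(
        name=scenario.name,
        cost=cost,
        burden=BurdenResult(
            yld=yld_total, yll=yll_total, deaths_averted=deaths_total
        ),
    )


def run_deterministic(
    base: Scenario,
    alternative: Scenario,
    population: PopulationProfile,
    catalog: Catalog,
    burden_settings: BurdenSettings,
    econ_settings: EconSettings,
    mortality: MortalityTable,
    bands: Mapping[str, "object"],
    coeffs: Mapping[str, MortalityCoefficients] | None = None,
) -> ComparisonResult:
    """Single evaluation of both scenarios with every parameter at its mean."""
    out0 = evaluate_scenario(
        base, population, catalog, burden_settings, mortality, bands, coeffs
    )
    out1 = evaluate_scenario(
        alternative, population, catalog, burden_settings, mortality, bands, coeffs
    )
    delta_c = out1.cost - out0.cost
    delta_e = out1.effect - out0.effect
    return ComparisonResult(
        base=out0,
        alternative=out1,
        icer=icer(delta_c, delta_e),
        wtp=econ_settings.wtp,
        bcr0=benefit_cost_ratio(out0.effect, out0.cost, econ_settings.wtp),
        bcr1=benefit_cost_ratio(out1.effect, out1.cost, econ_settings.wtp),
    )


def _draw_matrices(
    catalog: Catalog,
    burden_settings: BurdenSettings,
    psa: PsaSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All iterations' parameter draws, shared by both scenarios.

    Returns (n, k) cost and effect matrices whose columns follow the
    catalog's sorted (intervention, disorder) keys — the ordering that fixes
    the random stream for a given seed — plus the length-n conversion-factor
    vector.
    """
    n = psa.n_iterations
    cost_cols, effect_cols = [], []
    for iid, disorder in catalog.parameter_keys():
        spec = catalog[iid]
        cost_cols.append(
            sample_cost(cost_distribution(spec.cost_for(disorder)), rng, n)
        )
        effect_cols.append(
            sample_effect(effect_distribution(spec.effect_for(disorder)), rng, n)
        )
    if psa.sample_conversion_factor:
        lo, hi = burden_settings.conversion_factor_ci
        sd = (hi - lo) / 3.92
        cf = rng.normal(burden_settings.conversion_factor, sd, n)
    else:
        cf = np.full(n, burden_settings.conversion_factor)
    return np.column_stack(cost_cols), np.column_stack(effect_cols), cf


def run_psa(
    base: Scenario,
    alternative: Scenario,
    population: PopulationProfile,
    catalog: Catalog,
    burden_settings: BurdenSettings,
    econ_settings: EconSettings,
    mortality: MortalityTable,
    bands: Mapping[str, "object"],
    psa: PsaSettings,
    coeffs: Mapping[str, MortalityCoefficients] | None = None,
) -> PsaResult:
    """Seeded probabilistic sensitivity analysis.

    Per iteration one value is drawn per (intervention, disorder) cost and
    effect — plus, optionally, the conversion factor — and both scenarios are
    evaluated on those shared draws.  Identical seed and inputs reproduce the
    result bit for bit.

    Only costs and the YLD component vary with the draws; the mortality-side
    burden (deaths, YLL) depends on the intake-reduction fraction, which
    carries no published uncertainty range and is held fixed, so it is
    computed once per scenario and reused across iterations.
    """
    rng = np.random.default_rng(psa.seed)
    cost_draws, effect_draws, cf_draws = _draw_matrices(
        catalog, burden_settings, psa, rng
    )
    key_index = {k: j for j, k in enumerate(catalog.parameter_keys())}
    strata = stratify(population)
    band_counts = strata.groupby("band")["count"].sum()
    attn = 1.0 - burden_settings.attenuation

    def compile_scenario(scenario: Scenario):
        # draw-independent part via the full evaluation at parameter means
        outcome = evaluate_scenario(
            scenario, population, catalog, burden_settings, mortality, bands, coeffs
        )
        cols = np.array(
            [key_index[(e.intervention, e.disorder)] for e in scenario.entries],
            dtype=int,
        )
        covered = np.array(
            [
                float(band_counts.get(e.disorder, 0.0)) * e.coverage
                for e in scenario.entries
            ]
        )
        adherent = covered * np.array([e.adherence for e in scenario.entries])
        cost_vec = cost_draws[:, cols] @ covered
        yld_vec = (effect_draws[:, cols] @ adherent) * cf_draws * attn
        effect_vec = yld_vec + outcome.burden.yll
        return cost_vec, effect_vec

    c0, e0 = compile_scenario(base)
    c1, e1 = compile_scenario(alternative)
    delta_c = c1 - c0
    delta_e = e1 - e0
    icers = [icer(dc, de) for dc, de in zip(delta_c, delta_e)]
    frame = pd.DataFrame(
        {
            "iteration": np.arange(psa.n_iterations),
            "c0": c0,
            "c1": c1,
            "e0": e0,
            "e1": e1,
            "delta_c": delta_c,
            "delta_e": delta_e,
            "icer": [ic.value for ic in icers],
            "icer_flag": [ic.flag for ic in icers],
        }
    )
    numeric = ["c0", "c1", "e0", "e1", "delta_c", "delta_e", "icer"]
    summary = {
        col: {
            "mean": float(np.nanmean(frame[col].to_numpy()))
            if frame[col].notna().any()
            else float("nan"),
            "median": float(np.nanmedian(frame[col].to_numpy()))
            if frame[col].notna().any()
            else float("nan"),
        }
        for col in numeric
    }
    return PsaResult(iterations=frame, settings=psa, summary=summary)
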