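"""Health-economic aggregation: costs, ICER, CEAC, benefit-cost ratios.

Comparative outputs follow the standard incremental framework: with C0/E0 the
cost and effect (DALYs averted) of the base-case system and C1/E1 those of the
alternative, the incremental cost-effectiveness ratio is
ICER = (C1 - C0)/(E1 - E0), reported with explicit cost-effectiveness-plane
quadrant handling.  Decision uncertainty is summarised by the
cost-effectiveness acceptability curve: the probability, over probabilistic
draws, that the net monetary benefit lambda*dE - dC is positive for a grid of
willingness-to-pay ceilings lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interventions import Catalog, Scenario
from .population import PopulationProfile, stratify


@dataclass(frozen=True)
class EconSettings:
    """Willingness-to-pay settings.

    ``wtp`` is the euros-per-averted-DALY ceiling used for benefit-cost
    ratios (default 50,000, the conservative national lower bound);
    ``wtp_grid`` is the ceiling grid for the acceptability curve.
    """

    wtp: float = 50_000.0
    wtp_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(x) for x in range(0, 50_001, 1_000))
    )

    def __post_init__(self) -> None:
        if self.wtp < 0:
            raise ValueError("willingness to pay must be non-negative")
        grid = tuple(self.wtp_grid)
        if any(b < a for a, b in zip(grid, grid[1:])):
            raise ValueError("wtp_grid must be sorted ascending")


#: ICER quadrant labels
RATIO = "ratio"  # NE: more costly, more effective -> meaningful ratio
DOMINANT = "dominant"  # cheaper and at least as effective
DOMINATED = "dominated"  # costlier and no more effective
SW_RATIO = "sw_ratio"  # cheaper and less effective: raw ratio, tagged
UNDEFINED = "undefined"  # zero increment on both axes


@dataclass(frozen=True)
class Icer:
    """ICER value plus its cost-effectiveness-plane classification.

    ``value`` is NaN whenever a ratio is not meaningful (dominance or a zero
    increment); ``flag`` always identifies the quadrant.
    """

    value: float
    flag: str

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:
        if self.flag == RATIO:
            return f"Icer({self.value:.0f} €/DALY)"
        return f"Icer({self.flag})"


def icer(delta_c: float, delta_e: float) -> Icer:
    """Classify and compute the incremental cost-effectiveness ratio.

    Northeast quadrant (dC > 0, dE > 0) yields the ratio dC/dE.  A cheaper,
    no-less-effective alternative is dominant; a costlier, no-more-effective
    one is dominated.  The southwest quadrant (cheaper and less effective)
    reports the raw ratio under its own tag.  A zero increment on both axes
    is undefined.  Flags are returned, never raised.
    """
    if delta_c == 0 and delta_e == 0:
        return Icer(float("nan"), UNDEFINED)
    if delta_c > 0 and delta_e > 0:
        return Icer(delta_c / delta_e, RATIO)
    if delta_c <= 0 and delta_e >= 0:
        return Icer(float("nan"), DOMINANT)
    if delta_c >= 0 and delta_e <= 0:
        return Icer(float("nan"), DOMINATED)
    # delta_c < 0 and delta_e < 0
    return Icer(delta_c / delta_e, SW_RATIO)


def scenario_cost(
    scenario: Scenario,
    population: PopulationProfile,
    catalog: Catalog,
    cost_values: dict[tuple[str, str], float] | None = None,
) -> float:
    """Total annual cost of a scenario in euros.

    For every scenario entry, the stratum headcount of the targeted disorder
    class (men and women combined) is multiplied by the coverage rate and by
    the per-participant cost.  Costs accrue to everyone covered, adherent or
    not.  ``cost_values`` optionally substitutes drawn per-participant costs,
    keyed by (intervention id, disorder); the catalog point estimate is used
    otherwise.
    """
    scenario.validate_against(catalog)
    strata = stratify(population)
    band_counts = strata.groupby("band")["count"].sum()
    total = 0.0
    for entry in scenario.entries:
        if cost_values is not None:
            unit_cost = cost_values[(entry.intervention, entry.disorder)]
        else:
            unit_cost = catalog[entry.intervention].cost_for(entry.disorder).point
        count = float(band_counts.get(entry.disorder, 0.0))
        total += count * entry.coverage * unit_cost
    return total


def ceac(
    delta_c_draws: np.ndarray,
    delta_e_draws: np.ndarray,
    settings: EconSettings,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay ceiling lambda in the grid, the probability
    that the alternative is cost-effective is the fraction of draws with
    strictly positive net monetary benefit lambda*dE - dC.  The strict
    inequality anchors the curve at 0% for lambda = 0 when no draw is
    cost-saving.
    """
    dc = np.asarray(delta_c_draws, dtype=float)
    de = np.asarray(delta_e_draws, dtype=float)
    if dc.shape != de.shape or dc.ndim != 1:
        raise ValueError("delta_c and delta_e draw vectors must be 1-D and equal length")
    if dc.size == 0:
        raise ValueError("draw vectors must contain at least one iteration")
    grid = np.asarray(settings.wtp_grid, dtype=float)
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    probability = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid, "probability": probability})


def benefit_cost_ratio(effect: float, cost: float, wtp: float) -> float:
    """Euros of health value generated per euro spent.

    The averted DALYs are monetised at the willingness-to-pay ceiling and
    divided by the system cost; a ratio above 1 means every euro invested
    returns more than a euro of health-related value.
    """
    if cost <= 0:
        raise ValueError("cost must be positive to form a benefit-cost ratio")
    return effect * wtp / cost


def net_monetary_benefit(delta_c, delta_e, wtp: float):
    """lambda * dE - dC (vectorised)."""
    return wtp * np.asarray(delta_e, dtype=float) - np.asarray(delta_c, dtype=float)
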