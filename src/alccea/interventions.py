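"""Intervention catalog and scenario definitions.

An intervention is described, per targeted disorder class, by a per-participant
cost (point estimate plus an uncertainty range, 2009 euros) and a treatment
effect (standardized mean difference d with a 95% CI, plus the fraction by
which mean alcohol intake falls).  A scenario assigns a coverage rate and an
adherence rate to each (disorder, intervention) pair.

In probabilistic mode costs are drawn from a gamma distribution and effects
from a normal distribution; both are parameterised so that their mean equals
the point estimate and their standard deviation equals the stated range width
divided by 3.92 (the range is read as a central 95% interval).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .population import DISORDER_CLASSES

#: width of a central 95% interval in standard deviations
_Z95_WIDTH = 3.92

#: adherence applied to every intervention unless a scenario overrides it
DEFAULT_ADHERENCE = 0.50

#: default pre-post fractional reduction of mean alcohol intake
DEFAULT_INTAKE_REDUCTION = 0.20


class CatalogValidationError(ValueError):
    """Raised when a catalog or scenario file fails validation."""


@dataclass(frozen=True)
class CostSpec:
    """Per-participant cost of one intervention for one disorder class."""

    point: float
    low: float
    high: float
    currency_year: int = 2009

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high):
            raise CatalogValidationError(
                f"cost range [{self.low}, {self.high}] must bracket the "
                f"point estimate {self.point}"
            )
        if self.low <= 0:
            raise CatalogValidationError("costs must be positive")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / _Z95_WIDTH


@dataclass(frozen=True)
class EffectSpec:
    """Treatment effect of one intervention for one disorder class."""

    d: float
    ci_low: float
    ci_high: float
    intake_reduction: float = DEFAULT_INTAKE_REDUCTION

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.d <= self.ci_high):
            raise CatalogValidationError(
                f"effect CI [{self.ci_low}, {self.ci_high}] must bracket "
                f"d = {self.d}"
            )
        if not (0 <= self.intake_reduction < 1):
            raise CatalogValidationError("intake_reduction must lie in [0, 1)")

    @property
    def sd(self) -> float:
        return (self.ci_high - self.ci_low) / _Z95_WIDTH


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention with per-disorder costs and effects.

    Costs and effects are keyed by disorder class because the same
    intervention can have a different intensity (hence price and effect size)
    in different bands, e.g. therapist-led online treatment for harmful
    drinkers versus dependent drinkers.
    """

    id: str
    label: str = ""
    costs: Mapping[str, CostSpec] = field(default_factory=dict)
    effects: Mapping[str, EffectSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.costs:
            raise CatalogValidationError(
                f"intervention {self.id!r}: no applicable disorders"
            )
        for disorder in self.costs:
            if disorder not in DISORDER_CLASSES:
                raise CatalogValidationError(
                    f"intervention {self.id!r}: unknown disorder {disorder!r}"
                )
        if set(self.costs) != set(self.effects):
            raise CatalogValidationError(
                f"intervention {self.id!r}: cost and effect disorder sets differ"
            )

    @property
    def applicable_disorders(self) -> tuple[str, ...]:
        return tuple(d for d in DISORDER_CLASSES if d in self.costs)

    def cost_for(self, disorder: str) -> CostSpec:
        try:
            return self.costs[disorder]
        except KeyError:
            raise KeyError(
                f"intervention {self.id!r} is not applicable to {disorder!r}"
            ) from None

    def effect_for(self, disorder: str) -> EffectSpec:
        try:
            return self.effects[disorder]
        except KeyError:
            raise KeyError(
                f"intervention {self.id!r} is not applicable to {disorder!r}"
            ) from None


class Catalog:
    """Mapping of intervention id -> :class:`InterventionSpec`."""

    def __init__(self, interventions: Iterable[InterventionSpec]):
        self._by_id: dict[str, InterventionSpec] = {}
        for spec in interventions:
            if spec.id in self._by_id:
                raise CatalogValidationError(f"duplicate intervention id {spec.id!r}")
            self._by_id[spec.id] = spec

    def __getitem__(self, intervention_id: str) -> InterventionSpec:
        try:
            return self._by_id[intervention_id]
        except KeyError:
            raise KeyError(
                f"unknown intervention id {intervention_id!r}; catalog has "
                f"{sorted(self._by_id)}"
            ) from None

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, intervention_id: str) -> bool:
        return intervention_id in self._by_id

    def keys(self) -> list[str]:
        return sorted(self._by_id)

    def parameter_keys(self) -> list[tuple[str, str]]:
        """Sorted (intervention id, disorder) pairs: one cost and one effect
        parameter each.  The ordering fixes the random-draw sequence in
        probabilistic runs."""
        return sorted(
            (spec.id, disorder)
            for spec in self._by_id.values()
            for disorder in spec.applicable_disorders
        )

    def to_frame(self) -> pd.DataFrame:
        """Resolved catalog as a tidy table, one row per (id, disorder)."""
        rows = []
        for iid, disorder in self.parameter_keys():
            spec = self._by_id[iid]
            cost, effect = spec.cost_for(disorder), spec.effect_for(disorder)
            rows.append(
                {
                    "intervention": iid,
                    "label": spec.label,
                    "disorder": disorder,
                    "cost": cost.point,
                    "cost_low": cost.low,
                    "cost_high": cost.high,
                    "d": effect.d,
                    "d_ci_low": effect.ci_low,
                    "d_ci_high": effect.ci_high,
                    "intake_reduction": effect.intake_reduction,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioEntry:
    """Coverage of one intervention within one disorder class."""

    disorder: str
    intervention: str
    coverage: float
    adherence: float = DEFAULT_ADHERENCE

    def __post_init__(self) -> None:
        if self.disorder not in DISORDER_CLASSES:
            raise CatalogValidationError(f"unknown disorder {self.disorder!r}")
        if not (0 <= self.coverage <= 1):
            raise CatalogValidationError("coverage must lie in [0, 1]")
        if not (0 <= self.adherence <= 1):
            raise CatalogValidationError("adherence must lie in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """A health-care system: one coverage entry per (disorder, intervention)."""

    name: str
    entries: tuple[ScenarioEntry, ...]

    def __post_init__(self) -> None:
        pairs = [(e.disorder, e.intervention) for e in self.entries]
        if len(pairs) != len(set(pairs)):
            raise CatalogValidationError(
                f"scenario {self.name!r}: duplicate (disorder, intervention) pair"
            )

    def validate_against(self, catalog: Catalog) -> None:
        for entry in self.entries:
            spec = catalog[entry.intervention]  # raises KeyError if unknown
            if entry.disorder not in spec.applicable_disorders:
                raise CatalogValidationError(
                    f"scenario {self.name!r}: {entry.intervention!r} is not "
                    f"applicable to {entry.disorder!r}"
                )

    def with_coverage(
        self, disorder: str, intervention: str, coverage: float
    ) -> "Scenario":
        """Copy of the scenario with one entry's coverage replaced (adding the
        entry if absent) — the hook for what-if analyses."""
        entries = [
            e
            for e in self.entries
            if not (e.disorder == disorder and e.intervention == intervention)
        ]
        entries.append(
            ScenarioEntry(
                disorder=disorder, intervention=intervention, coverage=coverage
            )
        )
        return Scenario(name=self.name, entries=tuple(entries))


# ---------------------------------------------------------------------------
# sampling distributions


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale of the gamma cost distribution (moment-matched).

    A degenerate range is represented as ``scale == 0`` with the point mass
    recorded in ``point``.
    """

    shape: float
    scale: float
    point: float | None = None

    @property
    def mean(self) -> float:
        if self.scale == 0:
            return float(self.point)
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        if self.scale == 0:
            return 0.0
        return np.sqrt(self.shape) * self.scale


@dataclass(frozen=True)
class NormalParams:
    mean: float
    sd: float


def cost_distribution(cost: CostSpec) -> GammaParams:
    """Gamma distribution for a per-participant cost.

    Moment-matched so the mean equals the point estimate and the standard
    deviation equals (high - low)/3.92.  A degenerate range (low == high)
    yields a point mass, signalled by ``scale == 0``.
    """
    sd = cost.sd
    if sd == 0:
        return GammaParams(shape=np.inf, scale=0.0, point=cost.point)
    shape = cost.point**2 / sd**2
    scale = sd**2 / cost.point
    return GammaParams(shape=shape, scale=scale)


def effect_distribution(effect: EffectSpec) -> NormalParams:
    """Normal distribution for the effect size d (untruncated; CIs may cross
    zero, so negative draws are legitimate)."""
    return NormalParams(mean=effect.d, sd=effect.sd)


def sample_cost(params: GammaParams, rng: np.random.Generator, size=None):
    if params.scale == 0:
        # point mass; still consume one draw so the stream stays aligned
        u = rng.random(size)
        return params.mean + 0.0 * u
    return rng.gamma(params.shape, params.scale, size)


def sample_effect(params: NormalParams, rng: np.random.Generator, size=None):
    if params.sd == 0:
        u = rng.random(size)
        return params.mean + 0.0 * u
    return rng.normal(params.mean, params.sd, size)


def per_participant_cost(
    fixed_annual_costs: float,
    target_n: float,
    reach: float,
    uptake: float,
    variable_cost: float = 0.0,
) -> float:
    """Fold annual fixed costs of an intervention into a per-participant price.

    The number of participants is ``target_n * reach * uptake`` (population
    reached with information about the service times the response rate); the
    fixed annual costs (hosting, upgrades, moderation, ...) are spread over
    them and added to the variable per-participant cost.
    """
    participants = target_n * reach * uptake
    if participants < 1:
        raise ZeroDivisionError(
            "reach * uptake * target_n must amount to at least one participant"
        )
    return variable_cost + fixed_annual_costs / participants


# ---------------------------------------------------------------------------
# catalog / scenario (de)serialisation


def _catalog_from_mapping(data: Mapping) -> Catalog:
    if not isinstance(data, Mapping) or "interventions" not in data:
        raise CatalogValidationError(
            "catalog must be a mapping with an 'interventions' list"
        )
    specs = []
    for item in data["interventions"]:
        missing = {"id", "disorders"} - set(item)
        if missing:
            raise CatalogValidationError(
                f"intervention entry missing fields: {sorted(missing)}"
            )
        costs, effects = {}, {}
        for disorder, block in item["disorders"].items():
            missing = {"cost", "cost_low", "cost_high", "d", "d_ci_low", "d_ci_high"} - set(block)
            if missing:
                raise CatalogValidationError(
                    f"intervention {item['id']!r}/{disorder}: missing fields "
                    f"{sorted(missing)}"
                )
            costs[disorder] = CostSpec(
                point=float(block["cost"]),
                low=float(block["cost_low"]),
                high=float(block["cost_high"]),
                currency_year=int(block.get("currency_year", 2009)),
            )
            effects[disorder] = EffectSpec(
                d=float(block["d"]),
                ci_low=float(block["d_ci_low"]),
                ci_high=float(block["d_ci_high"]),
                intake_reduction=float(
                    block.get("intake_reduction", DEFAULT_INTAKE_REDUCTION)
                ),
            )
        specs.append(
            InterventionSpec(
                id=item["id"],
                label=item.get("label", ""),
                costs=costs,
                effects=effects,
            )
        )
    return Catalog(specs)


def load_catalog(path) -> Catalog:
    """Load an intervention catalog from a YAML file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        raise CatalogValidationError(f"catalog file {path} is empty")
    return _catalog_from_mapping(data)


def dump_catalog(catalog: Catalog, path=None) -> str:
    """Serialise a catalog to YAML (round-trips through :func:`load_catalog`)."""
    data = {
        "interventions": [
            {
                "id": spec.id,
                "label": spec.label,
                "disorders": {
                    disorder: {
                        "cost": spec.costs[disorder].point,
                        "cost_low": spec.costs[disorder].low,
                        "cost_high": spec.costs[disorder].high,
                        "currency_year": spec.costs[disorder].currency_year,
                        "d": spec.effects[disorder].d,
                        "d_ci_low": spec.effects[disorder].ci_low,
                        "d_ci_high": spec.effects[disorder].ci_high,
                        "intake_reduction": spec.effects[disorder].intake_reduction,
                    }
                    for disorder in spec.applicable_disorders
                },
            }
            for spec in sorted(catalog, key=lambda s: s.id)
        ]
    }
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_scenarios(path) -> dict[str, Scenario]:
    """Load named scenarios from a YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping) or "scenarios" not in data:
        raise CatalogValidationError(
            "scenario file must be a mapping with a 'scenarios' mapping"
        )
    out = {}
    for name, entries in data["scenarios"].items():
        out[name] = Scenario(
            name=name,
            entries=tuple(
                ScenarioEntry(
                    disorder=e["disorder"],
                    intervention=e["intervention"],
                    coverage=float(e["coverage"]),
                    adherence=float(e.get("adherence", DEFAULT_ADHERENCE)),
                )
                for e in entries
            ),
        )
    return out


def dump_scenarios(scenarios: Mapping[str, Scenario], path=None) -> str:
    data = {
        "scenarios": {
            name: [
                {
                    "disorder": e.disorder,
                    "intervention": e.intervention,
                    "coverage": e.coverage,
                    "adherence": e.adherence,
                }
                for e in scn.entries
            ]
            for name, scn in scenarios.items()
        }
    }
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def export_catalog_csv(catalog: Catalog, path=None) -> str:
    """CSV export of the resolved catalog (one row per id/disorder)."""
    buf = io.StringIO()
    catalog.to_frame().to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
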