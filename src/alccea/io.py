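"""Configuration, packaged fixtures, synthetic-input generation, and result
serialisation.

The package ships a Netherlands fixture set: the AUDIT-band composition of
the target population of problem drinkers, the calibrated band intakes with
their target relative risks, the intervention catalog (2009 euros, effect
sizes with 95% CIs), the three modeled coverage scenarios, and a synthetic
gender/age mortality and life-expectancy table.  The mortality fixture is
generated data — a Gompertz curve anchored on Dutch period life-table values
— not observed national statistics.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .burden import BurdenSettings
from .economics import EconSettings
from .engine import PsaSettings
from .interventions import Catalog, Scenario, load_catalog, load_scenarios
from .population import (
    GENDERS,
    AuditBand,
    MortalityTable,
    PopulationProfile,
    validate_bands,
)

FIXTURE_VERSION = "nl-2009-v1"

#: the three published totals of the Dutch target population (men, women);
#: "monitor" pairs with the AUDIT band fractions and is the default
POPULATION_PRESETS: dict[str, tuple[float, float]] = {
    "monitor": (987_000.0, 267_000.0),
    "national": (993_200.0, 222_800.0),
    # single combined total, split using the national gender ratio
    "combined": (
        1_255_000.0 * 993_200.0 / 1_216_000.0,
        1_255_000.0 * 222_800.0 / 1_216_000.0,
    ),
}


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file."""
    resource = importlib.resources.files("alccea").joinpath("data", name)
    return Path(str(resource))


def list_fixtures() -> list[str]:
    data_dir = importlib.resources.files("alccea").joinpath("data")
    return sorted(p.name for p in Path(str(data_dir)).iterdir() if p.is_file())


# ---------------------------------------------------------------------------
# fixture loaders


def load_band_definitions(path) -> dict[str, AuditBand]:
    """Load AUDIT band definitions (with calibrated per-gender intakes) from
    CSV with columns label, audit_min, audit_max, disorder_class,
    intake_men, intake_women."""
    frame = pd.read_csv(path, comment="#")
    bands = {}
    for _, row in frame.iterrows():
        bands[row["label"]] = AuditBand(
            label=row["label"],
            audit_min=int(row["audit_min"]),
            audit_max=int(row["audit_max"]),
            disorder_class=row["disorder_class"],
            mean_intake={
                "men": float(row["intake_men"]),
                "women": float(row["intake_women"]),
            },
        )
    validate_bands(bands.values())
    return bands


def bands_by_disorder(bands: Mapping[str, AuditBand]) -> dict[str, AuditBand]:
    """Re-key bands by disorder class, dropping the untargeted ones."""
    return {
        b.disorder_class: b for b in bands.values() if b.disorder_class != "none"
    }


def load_band_fractions(path) -> dict[str, dict[str, float]]:
    """Load per-gender band fractions from CSV (gender, band, fraction).

    Fractions are stored as proportions in [0, 1]; percent-style values
    (> 1) are rejected to avoid unit ambiguity.
    """
    frame = pd.read_csv(path, comment="#")
    missing = {"gender", "band", "fraction"} - set(frame.columns)
    if missing:
        raise ValueError(f"population file missing columns: {sorted(missing)}")
    if (frame["fraction"] > 1).any():
        raise ValueError(
            "band fractions must be proportions in [0, 1], not percentages"
        )
    out: dict[str, dict[str, float]] = {g: {} for g in GENDERS}
    for _, row in frame.iterrows():
        out[row["gender"]][row["band"]] = float(row["fraction"])
    return out


def write_band_fractions(fractions: Mapping[str, Mapping[str, float]], path) -> None:
    rows = [
        {"gender": g, "band": b, "fraction": f}
        for g in fractions
        for b, f in fractions[g].items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_population_profile(
    path,
    n_men: float,
    n_women: float,
    mean_age: float = 44.7,
    age_sd: float = 10.7,
) -> PopulationProfile:
    return PopulationProfile(
        n_men=n_men,
        n_women=n_women,
        band_fractions=load_band_fractions(path),
        mean_age=mean_age,
        age_sd=age_sd,
    )


# ---------------------------------------------------------------------------
# synthetic-data generators


@dataclass(frozen=True)
class GompertzParams:
    """Annual mortality rate ``level * exp(slope * age)``."""

    level: float
    slope: float


def life_expectancy_from_rates(rates: np.ndarray) -> np.ndarray:
    """Remaining life expectancy from annual death probabilities.

    Convention: the table's last age + 1 is the maximum attainable age —
    survival beyond it is not credited.  A person contributes a year for each
    whole year survived: ``e[a] = (1 - q[a]) * (1 + e[a + 1])`` with
    ``e`` zero past the end of the table.  Under a constant rate ``r`` this
    is the truncated geometric sum ``sum_{k=1..A-a} (1-r)^k`` and under a
    zero rate it is ``max_age - a``.
    """
    rates = np.asarray(rates, dtype=float)
    e = np.zeros(len(rates) + 1)
    for i in range(len(rates) - 1, -1, -1):
        e[i] = (1.0 - rates[i]) * (1.0 + e[i + 1])
    return e[:-1]


def generate_synthetic_mortality(
    params: Mapping[str, GompertzParams],
    age_range: tuple[int, int] = (18, 100),
) -> MortalityTable:
    """Synthetic gender/age mortality table with Gompertz-form rates.

    Rates increase exponentially with age; remaining life expectancy is
    derived from the generated rates by the period-life-table recursion of
    :func:`life_expectancy_from_rates`.  Parameters that push any rate above
    1 raise a ``ValueError``.
    """
    lo, hi = age_range
    ages = np.arange(lo, hi + 1)
    frames = []
    for gender, p in params.items():
        rates = p.level * np.exp(p.slope * ages)
        if np.any(rates > 1.0):
            raise ValueError(
                f"{gender}: Gompertz parameters yield rate > 1 before age {hi}"
            )
        if np.any(rates < 0.0):
            raise ValueError(f"{gender}: negative mortality rate")
        frames.append(
            pd.DataFrame(
                {
                    "gender": gender,
                    "age": ages,
                    "rate": rates,
                    "life_expectancy": life_expectancy_from_rates(rates),
                }
            )
        )
    return MortalityTable(pd.concat(frames, ignore_index=True))


#: NL-like Gompertz anchors (fit to 2009 Dutch period life-table rates around
#: ages 40-60); these generate the packaged synthetic mortality fixture
DEFAULT_GOMPERTZ = {
    "men": GompertzParams(level=1.80e-5, slope=0.1016),
    "women": GompertzParams(level=1.40e-5, slope=0.0996),
}


def generate_synthetic_audit_sample(
    n: int,
    band_fractions: Mapping[str, float],
    bands: Mapping[str, AuditBand],
    seed: int,
) -> np.ndarray:
    """Simulate per-person AUDIT scores for one gender.

    Band membership is multinomial with the given fractions; within a band
    the score is uniform over the band's integer range.  Emulates the kind of
    screening data a monitoring system would collect.
    """
    labels = list(band_fractions)
    p = np.asarray([band_fractions[b] for b in labels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("band fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0, dtype=int)
    assignments = rng.choice(len(labels), size=n, p=p)
    scores = np.empty(n, dtype=int)
    for i, band_idx in enumerate(assignments):
        band = bands[labels[band_idx]]
        scores[i] = rng.integers(band.audit_min, band.audit_max + 1)
    return scores


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs: fixture paths, scenario names, settings."""

    population_path: str
    bands_path: str
    catalog_path: str
    scenarios_path: str
    mortality_path: str
    base_scenario: str = "base_case"
    alt_scenario: str = "ehealth_added"
    population_preset: str = "monitor"
    n_men: float | None = None  # overrides the preset when set
    n_women: float | None = None
    mean_age: float = 44.7
    age_sd: float = 10.7
    mode: str = "deterministic"
    rr_second_term: str = "linear"
    burden: BurdenSettings = field(default_factory=BurdenSettings)
    econ: EconSettings = field(default_factory=EconSettings)
    psa: PsaSettings = field(default_factory=PsaSettings)

    def __post_init__(self) -> None:
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")
        if self.population_preset not in POPULATION_PRESETS:
            raise ValueError(
                f"unknown population preset {self.population_preset!r}; "
                f"choose from {sorted(POPULATION_PRESETS)}"
            )
        for attr in (
            "population_path",
            "bands_path",
            "catalog_path",
            "scenarios_path",
            "mortality_path",
        ):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise FileNotFoundError(f"{attr}: no such file {path!r}")

    @property
    def counts(self) -> tuple[float, float]:
        preset = POPULATION_PRESETS[self.population_preset]
        return (
            preset[0] if self.n_men is None else self.n_men,
            preset[1] if self.n_women is None else self.n_women,
        )


def default_config(**overrides) -> RunConfig:
    """RunConfig wired to the packaged Netherlands fixtures."""
    base = dict(
        population_path=str(fixture_path("population_nl.csv")),
        bands_path=str(fixture_path("audit_bands_nl.csv")),
        catalog_path=str(fixture_path("catalog_nl.yaml")),
        scenarios_path=str(fixture_path("scenarios_nl.yaml")),
        mortality_path=str(fixture_path("mortality_nl_synthetic.csv")),
    )
    base.update(overrides)
    return RunConfig(**base)


def _settings_to_dict(cfg: RunConfig) -> dict:
    return {
        "population_path": cfg.population_path,
        "bands_path": cfg.bands_path,
        "catalog_path": cfg.catalog_path,
        "scenarios_path": cfg.scenarios_path,
        "mortality_path": cfg.mortality_path,
        "base_scenario": cfg.base_scenario,
        "alt_scenario": cfg.alt_scenario,
        "population_preset": cfg.population_preset,
        "n_men": cfg.n_men,
        "n_women": cfg.n_women,
        "mean_age": cfg.mean_age,
        "age_sd": cfg.age_sd,
        "mode": cfg.mode,
        "rr_second_term": cfg.rr_second_term,
        "burden": {
            "conversion_factor": cfg.burden.conversion_factor,
            "conversion_factor_ci": list(cfg.burden.conversion_factor_ci),
            "attenuation": cfg.burden.attenuation,
            "horizon_months": cfg.burden.horizon_months,
        },
        "econ": {"wtp": cfg.econ.wtp, "wtp_grid": list(cfg.econ.wtp_grid)},
        "psa": {
            "n_iterations": cfg.psa.n_iterations,
            "seed": cfg.psa.seed,
            "sample_conversion_factor": cfg.psa.sample_conversion_factor,
        },
    }


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(_settings_to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    burden = data.pop("burden", {})
    econ = data.pop("econ", {})
    psa = data.pop("psa", {})
    if "conversion_factor_ci" in burden:
        burden["conversion_factor_ci"] = tuple(burden["conversion_factor_ci"])
    if "wtp_grid" in econ:
        econ["wtp_grid"] = tuple(econ["wtp_grid"])
    return RunConfig(
        burden=BurdenSettings(**burden),
        econ=EconSettings(**econ),
        psa=PsaSettings(**psa),
        **data,
    )


def settings_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration, for provenance."""
    payload = json.dumps(_settings_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class LoadedInputs:
    """All model inputs resolved from a RunConfig."""

    population: PopulationProfile
    bands: dict[str, AuditBand]
    catalog: Catalog
    scenarios: dict[str, Scenario]
    mortality: MortalityTable


def load_inputs(cfg: RunConfig) -> LoadedInputs:
    n_men, n_women = cfg.counts
    population = load_population_profile(
        cfg.population_path, n_men, n_women, cfg.mean_age, cfg.age_sd
    )
    bands = load_band_definitions(cfg.bands_path)
    catalog = load_catalog(cfg.catalog_path)
    scenarios = load_scenarios(cfg.scenarios_path)
    for scenario in scenarios.values():
        scenario.validate_against(catalog)
    mortality = MortalityTable.from_csv(cfg.mortality_path)
    # every band used by a scenario must resolve
    missing = {b for b in population.band_fractions["men"]} - set(bands)
    if missing:
        raise ValueError(f"population references unknown bands: {sorted(missing)}")
    return LoadedInputs(
        population=population,
        bands=bands,
        catalog=catalog,
        scenarios=scenarios,
        mortality=mortality,
    )


# ---------------------------------------------------------------------------
# result serialisation


def provenance(cfg: RunConfig, seed: int | None = None) -> dict:
    meta = {
        "fixture_version": FIXTURE_VERSION,
        "settings_hash": settings_hash(cfg),
    }
    if seed is not None:
        meta["seed"] = seed
    return meta


def write_frame_csv(frame: pd.DataFrame, path, meta: Mapping) -> None:
    """CSV with a provenance header of '# key: value' comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def write_json(payload: Mapping, path, meta: Mapping) -> None:
    path = Path(path)
    doc = {"provenance": dict(meta), **payload}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def config_with(cfg: RunConfig, **overrides) -> RunConfig:
    """Functional update helper (frozen dataclass)."""
    return replace(cfg, **overrides)
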