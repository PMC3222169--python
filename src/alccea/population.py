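"""Target population: AUDIT-band strata, age structure, and the alcohol
dose-response mortality risk.

The target group of problem drinkers is stratified by gender and by bands of
the Alcohol Use Disorders Identification Test (AUDIT, score 0-40).  Each band
carries a mean daily intake of pure ethanol (grams/day) from which the
relative risk (RR) of all-cause mortality is obtained through a two-parameter
dose-response curve.  Band intakes are not observed directly; they are
calibrated so that the curve reproduces published band-level RRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

GENDERS = ("men", "women")

#: disorder classes that interventions can target (band labels map onto these;
#: abstinent and moderate drinkers fall outside the treatment target group)
DISORDER_CLASSES = ("heavy", "hazardous", "harmful", "dependence")

# calibration search interval for band mean intake, grams pure ethanol/day
_INTAKE_LO = 0.0
_INTAKE_HI = 500.0


class CalibrationError(ValueError):
    """Raised when a target relative risk cannot be matched by the curve."""


@dataclass(frozen=True)
class MortalityCoefficients:
    """Gender-specific coefficients of the all-cause mortality dose-response.

    The curve is ``ln RR = b1*ln(x+1) + b2*x`` with ``x`` the mean intake of
    pure ethanol in grams/day.  ``b1 < 0`` produces the protective dip at
    moderate intake and ``b2 > 0`` the rising excess risk at high intake
    (the familiar J-shape).  The second term is linear in ``x``; a literal
    ``b2*ln(x)`` variant is available via ``second_term="log"`` for audit
    purposes, but it is undefined at ``x = 0`` and cannot return RR(0) = 1.
    """

    b1: float
    b2: float


#: default dose-response coefficients per gender
DOSE_RESPONSE: dict[str, MortalityCoefficients] = {
    "men": MortalityCoefficients(b1=-0.1030, b2=0.0035),
    "women": MortalityCoefficients(b1=-0.0645, b2=0.0029),
}


def relative_risk(
    intake: float | np.ndarray,
    coeffs: MortalityCoefficients,
    second_term: str = "linear",
) -> float | np.ndarray:
    """Relative risk of all-cause mortality at a given ethanol intake.

    Parameters
    ----------
    intake : float or array
        Mean pure-ethanol intake in grams/day, ``>= 0``.
    coeffs : MortalityCoefficients
        Gender-specific curve coefficients.
    second_term : {"linear", "log"}
        Functional form of the second term: ``b2*x`` (default) or the
        literal ``b2*ln(x)``, which diverges at zero intake.

    Returns
    -------
    float or ndarray
        ``RR >= 0``; exactly 1.0 at zero intake for the linear form.
    """
    x = np.asarray(intake, dtype=float)
    if np.any(x < 0):
        raise ValueError("intake must be non-negative (grams pure ethanol/day)")
    if second_term == "linear":
        log_rr = coeffs.b1 * np.log1p(x) + coeffs.b2 * x
    elif second_term == "log":
        with np.errstate(divide="ignore"):
            log_rr = coeffs.b1 * np.log1p(x) + coeffs.b2 * np.log(x)
    else:
        raise ValueError(f"unknown second_term: {second_term!r}")
    rr = np.exp(log_rr)
    if np.isscalar(intake) or np.ndim(intake) == 0:
        return float(rr)
    return rr


def _rr_minimum(coeffs: MortalityCoefficients) -> tuple[float, float]:
    """Location and value of the minimum of the J-shaped RR curve."""
    if coeffs.b2 <= 0 or coeffs.b1 >= 0:
        return 0.0, 1.0
    x_min = max(-coeffs.b1 / coeffs.b2 - 1.0, 0.0)
    return x_min, relative_risk(x_min, coeffs)


def calibrate_band_intake(
    target_rr: float,
    coeffs: MortalityCoefficients,
    band: str = "?",
    hi: float = _INTAKE_HI,
    tol: float = 1e-9,
) -> float:
    """Invert the dose-response curve: intake whose RR equals ``target_rr``.

    The curve is J-shaped, so targets below 1 have up to two roots.  The root
    on the increasing (high-intake) branch is returned so that calibrated
    intakes increase with band severity.  A target of exactly 1 maps to zero
    intake (the abstinent band).

    Raises
    ------
    CalibrationError
        If the target lies below the curve minimum or beyond its value at
        ``hi`` grams/day, naming the offending band.
    """
    if target_rr <= 0:
        raise CalibrationError(f"band {band!r}: target RR must be positive")
    if target_rr == 1.0:
        return 0.0
    x_min, rr_min = _rr_minimum(coeffs)
    if target_rr < rr_min - 1e-12:
        raise CalibrationError(
            f"band {band!r}: target RR {target_rr} lies below the curve "
            f"minimum {rr_min:.4f}; unattainable"
        )
    if target_rr > relative_risk(hi, coeffs):
        raise CalibrationError(
            f"band {band!r}: target RR {target_rr} exceeds RR({hi:g} g/day); "
            "unattainable on the search interval"
        )
    lo = x_min
    if relative_risk(lo, coeffs) >= target_rr:
        # target equals the minimum (within fp noise)
        return float(lo)
    root = optimize.brentq(
        lambda x: relative_risk(x, coeffs) - target_rr, lo, hi, xtol=tol
    )
    return float(root)


def calibrate_band_intakes(
    target_rr: Mapping[str, Mapping[str, float]],
    coeffs: Mapping[str, MortalityCoefficients] | None = None,
) -> dict[str, dict[str, float]]:
    """Calibrate mean intakes for every (gender, band) from target RRs.

    ``target_rr`` maps gender -> band label -> RR; the result has the same
    shape with grams/day values such that ``relative_risk`` round-trips each
    target to high precision.
    """
    coeffs = dict(DOSE_RESPONSE) if coeffs is None else dict(coeffs)
    out: dict[str, dict[str, float]] = {}
    for gender, bands in target_rr.items():
        out[gender] = {
            band: calibrate_band_intake(rr, coeffs[gender], band=band)
            for band, rr in bands.items()
        }
    return out


@dataclass(frozen=True)
class AuditBand:
    """One AUDIT score band of the target population.

    ``mean_intake`` maps gender to calibrated grams pure ethanol/day;
    ``disorder_class`` is ``"none"`` for bands outside the treatment target
    group (abstinent, moderate).
    """

    label: str
    audit_min: int
    audit_max: int
    disorder_class: str
    mean_intake: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.audit_min > self.audit_max:
            raise ValueError(f"band {self.label!r}: audit_min > audit_max")
        if any(v < 0 for v in self.mean_intake.values()):
            raise ValueError(f"band {self.label!r}: negative mean intake")
        if self.disorder_class not in DISORDER_CLASSES + ("none",):
            raise ValueError(
                f"band {self.label!r}: unknown disorder class "
                f"{self.disorder_class!r}"
            )


def validate_bands(bands: Iterable[AuditBand]) -> None:
    """Check that bands partition the AUDIT score range 0-40 without gaps."""
    ordered = sorted(bands, key=lambda b: b.audit_min)
    if not ordered:
        raise ValueError("no AUDIT bands defined")
    if ordered[0].audit_min != 0 or ordered[-1].audit_max != 40:
        raise ValueError("AUDIT bands must span scores 0 through 40")
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.audit_min != prev.audit_max + 1:
            raise ValueError(
                f"AUDIT bands {prev.label!r} and {nxt.label!r} do not tile "
                "the score range"
            )


@dataclass(frozen=True)
class PopulationProfile:
    """Size and composition of the target population.

    ``band_fractions`` maps gender -> band label -> fraction of that gender's
    target population; fractions must sum to 1 per gender.  The age structure
    is a normal distribution truncated to ``age_range`` and discretised to
    integer ages.
    """

    n_men: float
    n_women: float
    band_fractions: Mapping[str, Mapping[str, float]]
    mean_age: float = 44.7
    age_sd: float = 10.7
    age_range: tuple[int, int] = (18, 69)

    def __post_init__(self) -> None:
        if self.n_men < 0 or self.n_women < 0:
            raise ValueError("population counts must be non-negative")
        for gender in GENDERS:
            if gender not in self.band_fractions:
                raise ValueError(f"missing band fractions for {gender!r}")
            total = sum(self.band_fractions[gender].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{gender} band fractions sum to {total!r}, expected 1.0"
                )
            if any(f < 0 for f in self.band_fractions[gender].values()):
                raise ValueError(f"{gender} band fractions must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def count(self, gender: str) -> float:
        return {"men": self.n_men, "women": self.n_women}[gender]

    def scaled(self, factor: float) -> "PopulationProfile":
        """Same composition with all counts multiplied by ``factor``."""
        return PopulationProfile(
            n_men=self.n_men * factor,
            n_women=self.n_women * factor,
            band_fractions=self.band_fractions,
            mean_age=self.mean_age,
            age_sd=self.age_sd,
            age_range=self.age_range,
        )

    def age_weights(self) -> pd.Series:
        """Discretised truncated-normal age distribution on ``age_range``.

        Returns a Series indexed by integer age whose values sum to 1.
        """
        lo, hi = self.age_range
        ages = np.arange(lo, hi + 1)
        density = stats.norm.pdf(ages, loc=self.mean_age, scale=self.age_sd)
        weights = density / density.sum()
        return pd.Series(weights, index=ages, name="weight")


def stratify(profile: PopulationProfile) -> pd.DataFrame:
    """Expand a profile into a (gender, band, count) table.

    Counts are ``n_gender * fraction`` and conserve the total population.
    """
    rows = []
    for gender in GENDERS:
        n = profile.count(gender)
        for band, fraction in profile.band_fractions[gender].items():
            rows.append(
                {"gender": gender, "band": band, "count": n * fraction}
            )
    return pd.DataFrame(rows, columns=["gender", "band", "count"])


class MortalityTable:
    """Gender- and age-specific annual mortality and remaining life expectancy.

    Wraps a tidy frame with columns ``gender, age, rate, life_expectancy``.
    Rates are annual probabilities of dying; remaining life expectancy must be
    strictly decreasing in age within gender.
    """

    REQUIRED_COLUMNS = ("gender", "age", "rate", "life_expectancy")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.REQUIRED_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"mortality table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        frame["age"] = frame["age"].astype(int)
        if ((frame["rate"] < 0) | (frame["rate"] > 1)).any():
            raise ValueError("mortality rates must lie in [0, 1]")
        for gender, sub in frame.groupby("gender"):
            sub = sub.sort_values("age")
            if not sub["life_expectancy"].is_monotonic_decreasing:
                raise ValueError(
                    f"remaining life expectancy not decreasing in age ({gender})"
                )
            le = sub["life_expectancy"].to_numpy()
            if np.any(np.diff(le) >= 0):
                raise ValueError(
                    f"remaining life expectancy not strictly decreasing ({gender})"
                )
        self.frame = frame.sort_values(["gender", "age"]).reset_index(drop=True)
        self._by_gender = {
            gender: sub.set_index("age")
            for gender, sub in self.frame.groupby("gender")
        }

    def ages(self, gender: str) -> np.ndarray:
        return self._by_gender[gender].index.to_numpy()

    def _require(self, gender: str, ages: np.ndarray) -> pd.DataFrame:
        try:
            sub = self._by_gender[gender]
        except KeyError:
            raise KeyError(f"no mortality rows for gender {gender!r}") from None
        missing = np.setdiff1d(ages, sub.index.to_numpy())
        if missing.size:
            raise KeyError(
                f"mortality table lacks {gender} ages {missing.tolist()}"
            )
        return sub

    def rate(self, gender: str, age: int | np.ndarray) -> float | np.ndarray:
        ages = np.atleast_1d(np.asarray(age, dtype=int))
        sub = self._require(gender, ages)
        out = sub.loc[ages, "rate"].to_numpy()
        return float(out[0]) if np.ndim(age) == 0 else out

    def life_expectancy(
        self, gender: str, age: int | np.ndarray
    ) -> float | np.ndarray:
        ages = np.atleast_1d(np.asarray(age, dtype=int))
        sub = self._require(gender, ages)
        out = sub.loc[ages, "life_expectancy"].to_numpy()
        return float(out[0]) if np.ndim(age) == 0 else out

    def weighted_rate(self, gender: str, age_weights: pd.Series) -> float:
        """Age-distribution-weighted annual mortality rate m-bar."""
        ages = age_weights.index.to_numpy()
        rates = self.rate(gender, ages)
        return float(np.sum(age_weights.to_numpy() * rates))

    def death_weighted_life_expectancy(
        self, gender: str, age_weights: pd.Series
    ) -> float:
        """Mean remaining life expectancy at death for a population with the
        given age distribution: ages are weighted by ``weight * rate`` because
        deaths occur preferentially at the ages with higher mortality."""
        ages = age_weights.index.to_numpy()
        w = age_weights.to_numpy()
        rates = self.rate(gender, ages)
        le = self.life_expectancy(gender, ages)
        death_w = w * rates
        total = death_w.sum()
        if total == 0:
            return 0.0
        return float(np.sum(death_w * le) / total)

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, MortalityTable) and self.frame.equals(other.frame)
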