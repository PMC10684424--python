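"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates a three-city retrospective hip-fracture registry (counts by sex
and 5-year age band with Poisson noise around an exponential age gradient,
women overtaking men from about age 70), national demography, Gompertz
mortality, age-dependent ratios of non-hip major osteoporotic fracture
sites to hip fracture, and a set of dichotomous-risk-factor coefficients.
Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._piecewise import design_matrix
from .tables import (
    AGE_BANDS,
    RATE_DENOMINATOR,
    SEXES,
    Demography,
    LifeTable,
    band_midpoint,
)
from .probability_engine import CRF_NAMES, CRFEffect, RiskFactorModel

GENERATOR_VERSION = "1.0"

MOF_SITES = ("clinical_spine", "forearm", "humerus")


@dataclass(frozen=True)
class CityIncidenceSample:
    """Hip-fracture counts for one city, sex and 5-year age band."""

    city_name: str
    region: str
    sex: str
    age_lo: float
    age_hi: float
    fracture_count: int
    person_years: float

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.fracture_count < 0:
            raise ValueError("fracture counts must be non-negative")
        if self.person_years <= 0:
            raise ValueError("person-years must be positive")

    @property
    def rate(self) -> float:
        """Incidence per 100,000 person-years."""
        return self.fracture_count / self.person_years * RATE_DENOMINATOR


@dataclass(frozen=True)
class SexSpecificTruth:
    """True log incidence as a continuous piecewise-linear function of age:
    log rate(a) = intercept + slope_1*(a-50) accumulating extra slope at
    each breakpoint."""

    log_rate_at_50: float
    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]  # one per segment, len(breakpoints)+1

    def log_rate(self, age) -> np.ndarray:
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        coef = [self.log_rate_at_50 - self.slopes[0] * 50.0, self.slopes[0]]
        for s_prev, s_next in zip(self.slopes, self.slopes[1:]):
            coef.append(s_next - s_prev)
        out = design_matrix(age_arr, self.breakpoints) @ np.asarray(coef)
        return out if np.ndim(age) else float(out[0])

    def rate(self, age) -> np.ndarray:
        return np.exp(self.log_rate(age))


@dataclass(frozen=True)
class GroundTruthIncidence:
    """The generator's true hip-fracture rate surface λ(age, sex), per
    100,000 person-years, plus the stated female excess above age 70."""

    male: SexSpecificTruth
    female: SexSpecificTruth
    female_excess_factor_70plus: float = 1.5
    zero_rate: bool = False

    def rate(self, age, sex: str) -> np.ndarray:
        if self.zero_rate:
            return np.zeros_like(np.asarray(age, dtype=float))
        truth = self.male if sex == "male" else self.female
        return truth.rate(age)

    @classmethod
    def default(cls) -> "GroundTruthIncidence":
        """Brazil-like surface: rates in the tens per 100,000 in the 50s
        rising exponentially to ~1000+ in the 90s, men slightly ahead below
        age 70, women about 50% higher on average above 70."""
        male = SexSpecificTruth(
            log_rate_at_50=np.log(25.0),
            breakpoints=(62.0, 87.0),
            slopes=(0.065, 0.085, 0.075),
        )
        female = SexSpecificTruth(
            log_rate_at_50=np.log(22.5),
            breakpoints=(62.0, 82.0),
            slopes=(0.074, 0.107, 0.091),
        )
        return cls(male=male, female=female, female_excess_factor_70plus=1.5)

    @classmethod
    def zero(cls) -> "GroundTruthIncidence":
        base = cls.default()
        return cls(male=base.male, female=base.female, zero_rate=True)

    def to_dict(self) -> dict:
        return {
            "male": asdict(self.male),
            "female": asdict(self.female),
            "female_excess_factor_70plus": self.female_excess_factor_70plus,
            "zero_rate": self.zero_rate,
        }


def generate_city_incidence(
    truth: GroundTruthIncidence,
    cities: list[tuple[str, str, float]],
    person_years_per_band: float,
    seed: int,
) -> list[CityIncidenceSample]:
    """Draw Poisson fracture counts per city/sex/band.

    Counts are Poisson with mean scale * λ(band midpoint, sex) *
    person_years / 100,000, where ``scale`` is a per-city multiplier
    capturing regional differences in underlying risk.
    """
    if person_years_per_band <= 0:
        raise ValueError("person-years per band must be positive")
    rng = np.random.default_rng(seed)
    samples = []
    for city_name, region, scale in cities:
        if scale <= 0:
            raise ValueError(f"city scale must be positive ({city_name})")
        for sex in SEXES:
            for lo, hi in AGE_BANDS:
                mid = band_midpoint(lo, hi)
                lam = (
                    scale
                    * float(truth.rate(mid, sex))
                    * person_years_per_band
                    / RATE_DENOMINATOR
                )
                samples.append(
                    CityIncidenceSample(
                        city_name=city_name,
                        region=region,
                        sex=sex,
                        age_lo=lo,
                        age_hi=hi,
                        fracture_count=int(rng.poisson(lam)),
                        person_years=person_years_per_band,
                    )
                )
    return samples


def samples_to_frame(samples: list[CityIncidenceSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "city": [s.city_name for s in samples],
            "region": [s.region for s in samples],
            "sex": [s.sex for s in samples],
            "age_lo": [s.age_lo for s in samples],
            "age_hi": [s.age_hi for s in samples],
            "count": [s.fracture_count for s in samples],
            "person_years": [s.person_years for s in samples],
        }
    )


def generate_life_table(
    gompertz_a: float, gompertz_b: float, sex_offset: float, sex: str
) -> LifeTable:
    """Gompertz mortality: hazard(age) = a * exp(b*(age-50) + sex_offset)."""
    if gompertz_a <= 0 or gompertz_b < 0:
        raise ValueError("Gompertz parameters must be positive (b may be 0)")
    ages = np.arange(50, 111, dtype=float)
    hazard = gompertz_a * np.exp(gompertz_b * (ages - 50.0) + sex_offset)
    return LifeTable(sex=sex, ages=ages, hazard=hazard)


def generate_demography(
    total_population_50plus: int = 50_000_000, region: str = "National"
) -> Demography:
    """Deterministic national age/sex structure for the 50+ population.

    Cohort size decays ~22% per 5-year band (an ageing middle-income
    pyramid) and the female share rises from 52% at 50-54 to ~65% at 90+,
    reflecting the female survival advantage.
    """
    n_bands = len(AGE_BANDS)
    band_weights = np.exp(-0.25 * np.arange(n_bands))
    band_weights /= band_weights.sum()
    female_share = np.linspace(0.52, 0.65, n_bands)
    rows = []
    for i, (lo, hi) in enumerate(AGE_BANDS):
        total_band = total_population_50plus * band_weights[i]
        for sex, share in (
            ("male", 1.0 - female_share[i]),
            ("female", female_share[i]),
        ):
            rows.append(
                {
                    "region": region,
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "population": int(round(total_band * share)),
                }
            )
    return Demography(pd.DataFrame(rows))


def generate_ratio_table(sex: str) -> pd.DataFrame:
    """Age-dependent ratios of non-hip MOF site incidence to hip incidence.

    Mirrors the Swedish age pattern qualitatively: forearm fracture
    dominates in the 50s (ratios well above 1, especially in women) and
    hip dominates in the 80s, so the total MOF:hip ratio (1 + sum of site
    ratios) falls strictly with age.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    # site ratio at the 50-54 midpoint and exponential decline per year
    params = {
        "female": {
            "clinical_spine": (1.3, 0.035),
            "forearm": (4.0, 0.065),
            "humerus": (0.9, 0.030),
        },
        "male": {
            "clinical_spine": (1.1, 0.030),
            "forearm": (1.6, 0.055),
            "humerus": (0.7, 0.025),
        },
    }[sex]
    rows = []
    for lo, hi in AGE_BANDS:
        mid = band_midpoint(lo, hi)
        row = {"sex": sex, "age_lo": lo, "age_hi": hi}
        for site, (r0, decay) in params.items():
            row[site] = r0 * np.exp(-decay * (mid - 52.5))
        row["total_mof_to_hip"] = 1.0 + sum(row[s] for s in MOF_SITES)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_risk_factor_model(seed: int) -> RiskFactorModel:
    """Draw a plausible set of CRF coefficients and prevalences.

    Stands in for cohort-meta-analysis coefficients, which are not public:
    fracture RRs in [1.2, 2.5], death RRs in [1.0, 1.8], prevalences in
    [0.02, 0.35]; hip gradient of risk per SD in [1.4, 2.6], non-hip sites
    shallower in [1.2, 1.8].
    """
    rng = np.random.default_rng(seed)
    crfs = {}
    for name in CRF_NAMES:
        crfs[name] = CRFEffect(
            beta_fracture=float(rng.uniform(np.log(1.2), np.log(2.5))),
            beta_death=float(rng.uniform(np.log(1.0), np.log(1.8))),
            prevalence=float(rng.uniform(0.02, 0.35)),
        )
    return RiskFactorModel(
        crfs=crfs,
        gradient_hip=float(rng.uniform(1.4, 2.6)),
        gradient_other=float(rng.uniform(1.2, 1.8)),
        gradient_death=1.0,
        bmi_beta=0.03,
    )


# ---------------------------------------------------------------------------
# file round-trips: CSV with a '#'-prefixed metadata header, JSON for models


def _write_csv(frame: pd.DataFrame, path, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} generator_version={GENERATOR_VERSION}\n")
        frame.to_csv(fh, index=False)


def write_city_incidence_csv(samples, path, seed) -> None:
    _write_csv(samples_to_frame(samples), path, seed)


def read_city_incidence_csv(path) -> list[CityIncidenceSample]:
    frame = pd.read_csv(path, comment="#")
    return [
        CityIncidenceSample(
            city_name=row["city"],
            region=row["region"],
            sex=row["sex"],
            age_lo=float(row["age_lo"]),
            age_hi=float(row["age_hi"]),
            fracture_count=int(row["count"]),
            person_years=float(row["person_years"]),
        )
        for _, row in frame.iterrows()
    ]


def write_demography_csv(demography: Demography, path, seed) -> None:
    _write_csv(demography.frame, path, seed)


def read_demography_csv(path) -> Demography:
    return Demography(pd.read_csv(path, comment="#"))


def write_life_table_csv(table: LifeTable, path, seed) -> None:
    frame = pd.DataFrame(
        {"sex": table.sex, "age": table.ages, "hazard": table.hazard}
    )
    _write_csv(frame, path, seed)


def read_life_table_csv(path) -> LifeTable:
    frame = pd.read_csv(path, comment="#")
    (sex,) = frame["sex"].unique()
    return LifeTable(
        sex=sex,
        ages=frame["age"].to_numpy(dtype=float),
        hazard=frame["hazard"].to_numpy(dtype=float),
    )


def write_risk_factor_model_json(model: RiskFactorModel, path, seed) -> None:
    payload = {
        "seed": seed,
        "generator_version": GENERATOR_VERSION,
        "model": model.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_risk_factor_model_json(path) -> RiskFactorModel:
    with open(path) as fh:
        payload = json.load(fh)
    return RiskFactorModel.from_dict(payload["model"])
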