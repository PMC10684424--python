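"""Competing-risk 10-year fracture probability engine.

The engine follows the FRAX construction: an individual's annual fracture
and death hazards are a sex/age baseline multiplied by exp(sum of log
relative risks) over dichotomous clinical risk factors (CRFs), an optional
femoral-neck BMD term expressed through a gradient of risk per SD of
T-score, and (without BMD) a BMI term. Baselines are calibrated so that the
population-mean individual hazard reproduces the observed incidence and
mortality in every age group — the calibration rescales absolute risk
without altering the relative importance of the coefficients.

Ten-year probabilities integrate the fracture hazard against joint
fracture-free survival under competing death, in discrete steps with
hazards held constant within each step:

    P = sum_t S(t) * h_f/(h_f+h_d) * (1 - exp(-(h_f+h_d)*dt)),
    S(t+1) = S(t) * exp(-(h_f+h_d)*dt),  S(0) = 1.

The major-osteoporotic-fracture (MOF) outcome is the first-event composite
of hip and non-hip sites; its hazard is the sum of the hip hazard and the
combined non-hip (clinical spine, forearm, humerus) hazard, so the hip
probability can never exceed the MOF probability for the same profile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import SEXES, RATE_DENOMINATOR, AgeSexRateTable, LifeTable

CRF_NAMES = (
    "prior_fracture",
    "parent_hip_fracture",
    "smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "alcohol",
)

#: outcomes carrying their own baseline hazard
BASE_OUTCOMES = ("hip", "other", "death")

ENGINE_AGES = np.arange(50, 111)
REFERENCE_BMI = 25.0


@dataclass(frozen=True)
class CRFEffect:
    """One dichotomous clinical risk factor: log relative risks for fracture
    and death, and its population prevalence."""

    beta_fracture: float
    beta_death: float
    prevalence: float

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class RiskFactorModel:
    """The 'beta coefficients': CRF effects plus BMD/BMI terms.

    gradient_* are relative risks per SD decrease in femoral-neck T-score;
    ``bmi_beta`` is the fracture log-RR per kg/m^2 below the reference BMI
    of 25, applied only when no T-score is entered. The age-conditional
    T-score distribution used to integrate the BMD term is normal with mean
    ``tscore_mean_slope * (age - 50)`` and SD ``tscore_sd``.
    """

    crfs: dict[str, CRFEffect]
    gradient_hip: float
    gradient_other: float
    gradient_death: float = 1.0
    bmi_beta: float = 0.0
    tscore_mean_slope: float = -0.02
    tscore_sd: float = 1.0

    def __post_init__(self):
        for g in (self.gradient_hip, self.gradient_other, self.gradient_death):
            if g <= 0:
                raise ValueError("gradients of risk must be positive")

    def gradient(self, outcome: str) -> float:
        return {
            "hip": self.gradient_hip,
            "other": self.gradient_other,
            "death": self.gradient_death,
        }[outcome]

    def beta(self, crf: str, outcome: str) -> float:
        eff = self.crfs[crf]
        return eff.beta_death if outcome == "death" else eff.beta_fracture

    def tscore_mean(self, age) -> np.ndarray:
        return self.tscore_mean_slope * (np.asarray(age, dtype=float) - 50.0)

    def mean_bmd_factor(self, age, outcome: str) -> np.ndarray:
        """E[g^(-T)] over the age-conditional normal T-score distribution.

        With beta = log g and T ~ N(mu, sigma^2), the lognormal moment gives
        exp(-beta*mu + beta^2 sigma^2 / 2).
        """
        beta = np.log(self.gradient(outcome))
        mu = self.tscore_mean(age)
        return np.exp(-beta * mu + 0.5 * beta**2 * self.tscore_sd**2)

    def to_dict(self) -> dict:
        return {
            "crfs": {
                name: {
                    "beta_fracture": e.beta_fracture,
                    "beta_death": e.beta_death,
                    "prevalence": e.prevalence,
                }
                for name, e in self.crfs.items()
            },
            "gradient_hip": self.gradient_hip,
            "gradient_other": self.gradient_other,
            "gradient_death": self.gradient_death,
            "bmi_beta": self.bmi_beta,
            "tscore_mean_slope": self.tscore_mean_slope,
            "tscore_sd": self.tscore_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskFactorModel":
        crfs = {
            name: CRFEffect(**eff) for name, eff in d["crfs"].items()
        }
        kwargs = {k: v for k, v in d.items() if k != "crfs"}
        return cls(crfs=crfs, **kwargs)


@dataclass(frozen=True)
class RiskProfile:
    """One individual: age, sex, BMI, CRF indicators, optional T-score."""

    age: float
    sex: str
    bmi: float = REFERENCE_BMI
    crfs: tuple[str, ...] = ()
    tscore: float | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if not 40.0 <= self.age <= 90.0:
            raise ValueError("age must lie in [40, 90]")
        if not 15.0 <= self.bmi <= 45.0:
            raise ValueError("BMI must lie in [15, 45] kg/m^2")
        if self.tscore is not None and not -5.0 <= self.tscore <= 2.0:
            raise ValueError("T-score must lie in [-5, +2] when given")
        unknown = set(self.crfs) - set(CRF_NAMES)
        if unknown:
            raise ValueError(f"unknown CRFs: {sorted(unknown)}")

    def indicator(self) -> np.ndarray:
        return np.array([float(c in self.crfs) for c in CRF_NAMES])


def population_mean_rr(
    model: RiskFactorModel, age, sex: str, outcome: str
) -> float:
    """Population-mean relative risk E[exp(beta . x)] at one age/sex.

    CRFs are independent Bernoullis, so the expectation factorises into
    prod_c (1 - p_c + p_c * exp(beta_c)); the BMD term is integrated over
    the age-conditional normal T-score distribution.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    prod = 1.0
    for name in model.crfs:
        eff = model.crfs[name]
        beta = model.beta(name, outcome)
        prod *= 1.0 - eff.prevalence + eff.prevalence * np.exp(beta)
    return float(prod * model.mean_bmd_factor(age, outcome))


def _interp_positive(x_known, y_known, x_new) -> np.ndarray:
    """Interpolate strictly positive y log-linearly in x, extrapolating the
    terminal segment slopes beyond the known range."""
    x_known = np.asarray(x_known, dtype=float)
    logy = np.log(np.asarray(y_known, dtype=float))
    x_new = np.asarray(x_new, dtype=float)
    out = np.interp(x_new, x_known, logy)
    if x_known.size >= 2:
        lo_slope = (logy[1] - logy[0]) / (x_known[1] - x_known[0])
        hi_slope = (logy[-1] - logy[-2]) / (x_known[-1] - x_known[-2])
        below = x_new < x_known[0]
        above = x_new > x_known[-1]
        out[below] = logy[0] + lo_slope * (x_new[below] - x_known[0])
        out[above] = logy[-1] + hi_slope * (x_new[above] - x_known[-1])
    return np.exp(out)


def _band_rates_to_age_hazard(table: AgeSexRateTable, sex: str) -> np.ndarray:
    """Band-level rates per 100,000 -> annual hazard at each engine age."""
    mids = table.midpoints(sex)
    rates = table.rates(sex)
    pos = rates > 0
    haz = np.zeros(ENGINE_AGES.size)
    if pos.sum() >= 2:
        haz[:] = _interp_positive(mids[pos], rates[pos], ENGINE_AGES)
    elif pos.sum() == 1:
        haz[:] = rates[pos][0]
    if not pos.all():
        # ages inside zero-rate bands keep a zero hazard
        for (lo, hi), r in zip(
            zip(
                table.frame.loc[table.frame["sex"] == sex, "age_lo"],
                table.frame.loc[table.frame["sex"] == sex, "age_hi"],
            ),
            rates,
        ):
            if r == 0:
                haz[(ENGINE_AGES >= lo) & (ENGINE_AGES < hi)] = 0.0
    return haz / RATE_DENOMINATOR


@dataclass(frozen=True)
class CalibratedModel:
    """Baseline hip / non-hip MOF / death hazards per sex and integer age,
    together with the risk-factor model they were calibrated against.

    Baselines satisfy the calibration identity
    h0(a) * population_mean_rr(a) == observed hazard(a) exactly at every
    engine age, by construction.
    """

    risk_model: RiskFactorModel
    baselines: dict[str, dict[str, np.ndarray]]  # sex -> outcome -> hazards
    ages: np.ndarray = field(default_factory=lambda: ENGINE_AGES.copy())

    def baseline(self, sex: str, outcome: str) -> np.ndarray:
        return self.baselines[sex][outcome]

    def baseline_at(self, sex: str, outcome: str, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]):
            raise ValueError(
                f"attained age outside calibrated range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        h0 = self.baselines[sex][outcome]
        if np.all(h0 > 0):
            return np.exp(np.interp(age, self.ages, np.log(h0)))
        return np.interp(age, self.ages, h0)

    def population_mean_hazard(self, sex: str, outcome: str, age) -> np.ndarray:
        mean_rr = np.array(
            [
                population_mean_rr(self.risk_model, a, sex, outcome)
                for a in np.atleast_1d(np.asarray(age, dtype=float))
            ]
        )
        out = self.baseline_at(sex, outcome, age) * mean_rr
        return out if np.ndim(age) else float(out[0])

    def scaled_incidence(self, factor: float) -> "CalibratedModel":
        """A model identical except all fracture baselines scaled by factor."""
        new = {
            sex: {
                "hip": b["hip"] * factor,
                "other": b["other"] * factor,
                "death": b["death"].copy(),
            }
            for sex, b in self.baselines.items()
        }
        return replace(self, baselines=new)

    def to_dict(self) -> dict:
        return {
            "ages": self.ages.tolist(),
            "baselines": {
                sex: {k: v.tolist() for k, v in b.items()}
                for sex, b in self.baselines.items()
            },
            "risk_model": self.risk_model.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedModel":
        return cls(
            risk_model=RiskFactorModel.from_dict(d["risk_model"]),
            baselines={
                sex: {k: np.asarray(v, dtype=float) for k, v in b.items()}
                for sex, b in d["baselines"].items()
            },
            ages=np.asarray(d["ages"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "CalibratedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate(
    incidence_hip: AgeSexRateTable,
    incidence_mof: AgeSexRateTable,
    life_tables: dict[str, LifeTable],
    model: RiskFactorModel,
) -> CalibratedModel:
    """Calibrate baseline hazards to population incidence and mortality.

    For each sex and integer age a the observed hazard (band rates
    interpolated log-linearly to integer ages; life-table hazards for
    death) is divided by the population-mean relative risk, so that
    averaging individual hazards over the CRF/T-score distribution
    recovers the observed hazard exactly. The non-hip MOF hazard is the
    combined MOF hazard minus the hip hazard.
    """
    baselines: dict[str, dict[str, np.ndarray]] = {}
    for sex in incidence_hip.sexes():
        hip = _band_rates_to_age_hazard(incidence_hip, sex)
        mof = _band_rates_to_age_hazard(incidence_mof, sex)
        other = mof - hip
        if np.any(other < -1e-12):
            raise ValueError("combined MOF rates must dominate hip rates")
        other = np.maximum(other, 0.0)
        death = life_tables[sex].hazard_at(ENGINE_AGES)
        per_outcome = {}
        for outcome, observed in (
            ("hip", hip),
            ("other", other),
            ("death", death),
        ):
            mean_rr = np.array(
                [
                    population_mean_rr(model, a, sex, outcome)
                    for a in ENGINE_AGES
                ]
            )
            h0 = observed / mean_rr
            if np.any((observed == 0) & (mean_rr > 0)) and outcome != "other":
                warnings.warn(
                    f"zero observed {outcome} hazard for {sex}; "
                    "baseline set to 0 at those ages",
                    stacklevel=2,
                )
            per_outcome[outcome] = h0
        baselines[sex] = per_outcome
    return CalibratedModel(risk_model=model, baselines=baselines)


def _profile_rr(
    model: RiskFactorModel,
    outcome: str,
    indicators: np.ndarray,
    tscore,
    bmi,
    age,
) -> np.ndarray:
    """Vectorised relative risk over profiles at (possibly vector) age."""
    betas = np.array([model.beta(c, outcome) for c in CRF_NAMES])
    rr = np.exp(indicators @ betas)
    g = model.gradient(outcome)
    tscore = np.asarray(tscore, dtype=float)
    has_t = ~np.isnan(tscore)
    bmd = np.where(has_t, g ** (-np.where(has_t, tscore, 0.0)), 1.0)
    rr = rr * bmd
    no_t_factor = model.mean_bmd_factor(age, outcome)
    rr = rr * np.where(has_t, 1.0, no_t_factor)
    if outcome != "death":
        bmi_rr = np.exp(model.bmi_beta * (REFERENCE_BMI - np.asarray(bmi)))
        rr = rr * np.where(has_t, 1.0, bmi_rr)
    return rr


def individual_hazard(
    model: CalibratedModel,
    profile: RiskProfile,
    outcome: str,
    attained_age: float,
) -> float:
    """Annual hazard for one profile at an attained age.

    outcome 'mof' is the sum of the hip and non-hip site hazards.
    """
    if outcome == "mof":
        return individual_hazard(
            model, profile, "hip", attained_age
        ) + individual_hazard(model, profile, "other", attained_age)
    ind = profile.indicator()[None, :]
    t = np.nan if profile.tscore is None else profile.tscore
    rr = _profile_rr(
        model.risk_model, outcome, ind, [t], [profile.bmi], attained_age
    )
    h0 = model.baseline_at(profile.sex, outcome, attained_age)
    return float(h0 * rr[0])


def _ten_year_batch(
    model: CalibratedModel,
    age: np.ndarray,
    sex: str,
    indicators: np.ndarray,
    tscore: np.ndarray,
    bmi: np.ndarray,
    outcome: str,
    step: str,
) -> np.ndarray:
    if outcome not in ("hip", "mof"):
        raise ValueError("outcome must be 'hip' or 'mof'")
    if step not in ("annual", "monthly"):
        raise ValueError("step must be 'annual' or 'monthly'")
    dt = 1.0 if step == "annual" else 1.0 / 12.0
    n_steps = int(round(10.0 / dt))
    rm = model.risk_model
    surv = np.ones(age.shape)
    prob = np.zeros(age.shape)
    for k in range(n_steps):
        attained = age + k * dt
        h_hip = model.baseline_at(sex, "hip", attained) * _profile_rr(
            rm, "hip", indicators, tscore, bmi, attained
        )
        if outcome == "mof":
            h_f = h_hip + model.baseline_at(sex, "other", attained) * _profile_rr(
                rm, "other", indicators, tscore, bmi, attained
            )
        else:
            h_f = h_hip
        h_d = model.baseline_at(sex, "death", attained) * _profile_rr(
            rm, "death", indicators, tscore, bmi, attained
        )
        total = h_f + h_d
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_share = np.where(total > 0, h_f / np.where(total > 0, total, 1.0), 0.0)
        prob += surv * frac_share * (1.0 - np.exp(-total * dt))
        surv *= np.exp(-total * dt)
    return prob


def ten_year_probability(
    model: CalibratedModel,
    profile: RiskProfile,
    outcome: str = "hip",
    step: str = "annual",
) -> float:
    """10-year probability of a first hip or MOF fracture under competing
    death, for one risk profile."""
    t = np.nan if profile.tscore is None else profile.tscore
    out = _ten_year_batch(
        model,
        np.array([float(profile.age)]),
        profile.sex,
        profile.indicator()[None, :],
        np.array([t]),
        np.array([float(profile.bmi)]),
        outcome,
        step,
    )
    return float(out[0])


def ten_year_probabilities(
    model: CalibratedModel,
    profiles: pd.DataFrame,
    outcome: str = "hip",
    step: str = "annual",
) -> np.ndarray:
    """Vectorised 10-year probabilities for a profile table.

    ``profiles`` needs columns age, sex, bmi, tscore (NaN = no BMD) and one
    0/1 column per CRF name.
    """
    out = np.empty(len(profiles))
    for sex, grp in profiles.groupby("sex", sort=False):
        idx = grp.index.to_numpy()
        out[profiles.index.get_indexer(idx)] = _ten_year_batch(
            model,
            grp["age"].to_numpy(dtype=float),
            sex,
            grp[list(CRF_NAMES)].to_numpy(dtype=float),
            grp["tscore"].to_numpy(dtype=float),
            grp["bmi"].to_numpy(dtype=float),
            outcome,
            step,
        )
    return out
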