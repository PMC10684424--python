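"""Shared builders for test fixtures: flat tables, null risk models, and a
small calibrated model constructed from the synthetic generators."""

from __future__ import annotations

import numpy as np

from fraxforge.probability_engine import (
    CRF_NAMES,
    CRFEffect,
    CalibratedModel,
    RiskFactorModel,
    calibrate,
)
from fraxforge.synthetic_data import (
    GroundTruthIncidence,
    generate_life_table,
    generate_ratio_table,
    generate_risk_factor_model,
)
from fraxforge.incidence_synthesis import impute_mof_rates
from fraxforge.tables import AGE_BANDS, AgeSexRateTable, LifeTable, band_midpoints


def flat_rate_table(rate: float, rate_female: float | None = None) -> AgeSexRateTable:
    n = len(AGE_BANDS)
    return AgeSexRateTable.from_rates(
        {
            "male": np.full(n, rate),
            "female": np.full(n, rate if rate_female is None else rate_female),
        }
    )


def truth_rate_table(truth: GroundTruthIncidence) -> AgeSexRateTable:
    mids = band_midpoints()
    return AgeSexRateTable.from_rates(
        {sex: truth.rate(mids, sex) for sex in ("male", "female")}
    )


def const_life_table(hazard: float, sex: str) -> LifeTable:
    ages = np.arange(50, 111, dtype=float)
    return LifeTable(sex=sex, ages=ages, hazard=np.full(ages.size, hazard))


def null_risk_model(prevalence: float = 0.1) -> RiskFactorModel:
    """All coefficients zero: every profile has relative risk 1."""
    crfs = {
        name: CRFEffect(beta_fracture=0.0, beta_death=0.0, prevalence=prevalence)
        for name in CRF_NAMES
    }
    return RiskFactorModel(
        crfs=crfs,
        gradient_hip=1.0,
        gradient_other=1.0,
        gradient_death=1.0,
        bmi_beta=0.0,
        tscore_mean_slope=0.0,
    )


def single_crf_model(prevalence: float, rr: float, rr_death: float = 1.0) -> RiskFactorModel:
    crfs = {
        name: CRFEffect(beta_fracture=0.0, beta_death=0.0, prevalence=0.0)
        for name in CRF_NAMES
    }
    crfs["prior_fracture"] = CRFEffect(
        beta_fracture=float(np.log(rr)),
        beta_death=float(np.log(rr_death)),
        prevalence=prevalence,
    )
    return RiskFactorModel(
        crfs=crfs,
        gradient_hip=1.0,
        gradient_other=1.0,
        gradient_death=1.0,
        bmi_beta=0.0,
        tscore_mean_slope=0.0,
    )


def fracture_only_risk_model(seed: int = 11) -> RiskFactorModel:
    """Generated coefficients with every death effect removed, so all
    profiles share the same death relative risk."""
    base = generate_risk_factor_model(seed)
    crfs = {
        name: CRFEffect(
            beta_fracture=eff.beta_fracture, beta_death=0.0, prevalence=eff.prevalence
        )
        for name, eff in base.crfs.items()
    }
    return RiskFactorModel(
        crfs=crfs,
        gradient_hip=base.gradient_hip,
        gradient_other=base.gradient_other,
        gradient_death=1.0,
        bmi_beta=base.bmi_beta,
        tscore_mean_slope=base.tscore_mean_slope,
        tscore_sd=base.tscore_sd,
    )


def constant_hazard_model(
    h_frac: float, h_death: float, h_other: float = 0.0
) -> CalibratedModel:
    """Calibrated model with flat baselines and a null risk model, so every
    profile sees exactly (h_frac, h_other, h_death)."""
    ages = np.arange(50, 111, dtype=float)
    baselines = {
        sex: {
            "hip": np.full(ages.size, h_frac),
            "other": np.full(ages.size, h_other),
            "death": np.full(ages.size, h_death),
        }
        for sex in ("male", "female")
    }
    return CalibratedModel(
        risk_model=null_risk_model(), baselines=baselines, ages=ages
    )


def make_calibrated_model(seed: int = 7, incidence_scale: float = 1.0) -> CalibratedModel:
    """Realistic small model: default ground-truth incidence, Gompertz
    mortality, generated coefficients."""
    hip = truth_rate_table(GroundTruthIncidence.default()).scaled(incidence_scale)
    ratios = {sex: generate_ratio_table(sex) for sex in ("male", "female")}
    mof = impute_mof_rates(hip, ratios)["mof"]
    life = {
        "male": generate_life_table(0.004, 0.085, 0.45, "male"),
        "female": generate_life_table(0.004, 0.085, 0.0, "female"),
    }
    return calibrate(hip, mof, life, generate_risk_factor_model(seed))
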