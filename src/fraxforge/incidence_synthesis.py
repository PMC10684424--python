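"""From city-level registry counts to a smoothed national incidence surface.

City rates are combined as a convex combination weighted by the population
share of each city's region; log incidence is smoothed against band-midpoint
age with a continuous piecewise-linear (segmented) regression with fixed
breakpoints; the national annual burden is the rate surface applied to
national demography; and rates for the non-hip major osteoporotic fracture
sites are imputed by multiplying the hip rates with external site:hip
ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._piecewise import ContinuousPiecewiseFit, fit_continuous_piecewise
from .tables import (
    RATE_DENOMINATOR,
    AgeSexRateTable,
    Demography,
    band_midpoint,
)
from .synthetic_data import MOF_SITES, CityIncidenceSample

#: segmented-regression breakpoints (years of age) per sex
DEFAULT_BREAKPOINTS = {"male": (62.0, 87.0), "female": (62.0, 82.0)}

AGE_RANGE = (50.0, 110.0)


@dataclass(frozen=True)
class RegionWeights:
    """Population share per region, renormalised over the regions present."""

    weights: dict[str, float]

    def __post_init__(self):
        if not self.weights:
            raise ValueError("at least one region weight is required")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("region weights must be non-negative")
        if sum(self.weights.values()) <= 0:
            raise ValueError("region weights must not all be zero")

    def normalised(self, regions=None) -> dict[str, float]:
        keys = list(self.weights) if regions is None else list(regions)
        missing = [r for r in keys if r not in self.weights]
        if missing:
            raise KeyError(f"no weight for regions {missing}")
        total = sum(self.weights[r] for r in keys)
        if total <= 0:
            raise ValueError("selected regions have zero total weight")
        return {r: self.weights[r] / total for r in keys}


#: the three covered regions' national population shares
BRAZIL_REGION_WEIGHTS = RegionWeights(
    {"Southeast": 0.42, "Northeast": 0.28, "South": 0.14}
)


def combine_regions(
    samples: list[CityIncidenceSample], weights: RegionWeights
) -> AgeSexRateTable:
    """Region-weighted national rate per band/sex.

    Each region must be represented by exactly one city; its rate stands
    for the whole region. The combined rate is the weighted mean of city
    rates with weights renormalised over the regions present, hence a
    convex combination bounded by the city minima and maxima.
    """
    frame = pd.DataFrame(
        {
            "region": [s.region for s in samples],
            "city": [s.city_name for s in samples],
            "sex": [s.sex for s in samples],
            "age_lo": [s.age_lo for s in samples],
            "age_hi": [s.age_hi for s in samples],
            "rate": [s.rate for s in samples],
        }
    )
    for region, grp in frame.groupby("region"):
        if grp["city"].nunique() != 1:
            raise ValueError(
                f"region {region!r} must be represented by exactly one city"
            )
    regions = sorted(frame["region"].unique())
    norm = weights.normalised(regions)

    band_sets = {
        city: set(zip(grp["sex"], grp["age_lo"]))
        for city, grp in frame.groupby("city")
    }
    ref = next(iter(band_sets.values()))
    if any(bands != ref for bands in band_sets.values()):
        raise ValueError("cities report different sex/age-band structures")

    frame["w"] = frame["region"].map(norm)
    combined = (
        frame.assign(wrate=frame["w"] * frame["rate"])
        .groupby(["sex", "age_lo", "age_hi"], as_index=False)[["wrate"]]
        .sum()
        .rename(columns={"wrate": "rate"})
    )
    return AgeSexRateTable(combined)


@dataclass(frozen=True)
class PiecewiseLogLinearFit:
    """Segmented straight-line fit of log incidence on age for one sex."""

    sex: str
    fit: ContinuousPiecewiseFit
    zero_policy: str = "exclude"

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return self.fit.knots

    @property
    def segment_slopes(self) -> tuple[float, ...]:
        return self.fit.segment_slopes

    @property
    def segment_intercepts(self) -> tuple[float, ...]:
        return self.fit.segment_intercepts

    @property
    def rss(self) -> float:
        return self.fit.rss

    def continuity_residuals(self) -> tuple[float, ...]:
        return self.fit.continuity_residuals()

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "breakpoints": list(self.fit.knots),
            "coef": list(self.fit.coef),
            "rss": self.fit.rss,
            "n_points": self.fit.n_points,
            "zero_policy": self.zero_policy,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseLogLinearFit":
        fit = ContinuousPiecewiseFit(
            knots=tuple(d["breakpoints"]),
            coef=tuple(d["coef"]),
            rss=d["rss"],
            n_points=d["n_points"],
        )
        return cls(sex=d["sex"], fit=fit, zero_policy=d["zero_policy"])


def fit_piecewise_loglinear(
    table: AgeSexRateTable,
    breakpoints,
    sex: str,
    zero_policy: str = "exclude",
    count_weights=None,
) -> PiecewiseLogLinearFit:
    """Least-squares continuous piecewise-linear fit of log rate on band
    midpoint age.

    zero_policy 'exclude' drops zero-rate bands from the regression;
    'add-half' replaces a zero rate with half the smallest positive rate.
    ``count_weights`` optionally weights bands (e.g. by fracture counts).
    """
    ages = table.midpoints(sex)
    rates = table.rates(sex)
    weights = None if count_weights is None else np.asarray(count_weights, float)
    zero = rates <= 0
    if zero.any():
        if zero_policy == "exclude":
            keep = ~zero
            ages, rates = ages[keep], rates[keep]
            if weights is not None:
                weights = weights[keep]
        elif zero_policy == "add-half":
            rates = np.where(zero, rates[~zero].min() / 2.0, rates)
        else:
            raise ValueError(
                "non-positive rates present; zero_policy must be "
                "'exclude' or 'add-half'"
            )
    fit = fit_continuous_piecewise(ages, np.log(rates), breakpoints, weights)
    return PiecewiseLogLinearFit(sex=sex, fit=fit, zero_policy=zero_policy)


def fit_both_sexes(
    table: AgeSexRateTable,
    breakpoints_by_sex: dict[str, tuple[float, ...]] = DEFAULT_BREAKPOINTS,
    **kwargs,
) -> dict[str, PiecewiseLogLinearFit]:
    return {
        sex: fit_piecewise_loglinear(table, bp, sex, **kwargs)
        for sex, bp in breakpoints_by_sex.items()
    }


def predict_rate(fit: PiecewiseLogLinearFit, age, sex: str | None = None):
    """Smoothed incidence per 100,000 at ``age`` (50-110 years)."""
    if sex is not None and sex != fit.sex:
        raise ValueError(f"fit is for sex {fit.sex!r}, not {sex!r}")
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(age_arr < AGE_RANGE[0]) or np.any(age_arr > AGE_RANGE[1]):
        raise ValueError(f"age outside supported range {AGE_RANGE}")
    out = np.exp(fit.fit.predict(age_arr))
    return out if np.ndim(age) else float(out[0])


def smoothed_rate_table(
    fits: dict[str, PiecewiseLogLinearFit]
) -> AgeSexRateTable:
    """Rate table re-evaluated from the fits at the band midpoints."""
    rates = {}
    for sex, fit in fits.items():
        from .tables import band_midpoints

        rates[sex] = predict_rate(fit, band_midpoints())
    return AgeSexRateTable.from_rates(rates)


@dataclass(frozen=True)
class NationalBurden:
    """Expected annual fracture counts nationwide."""

    men: float
    women: float

    @property
    def total(self) -> float:
        return self.men + self.women

    @property
    def male_share(self) -> float:
        """Male fraction of the total burden."""
        return self.men / self.total

    @classmethod
    def from_total_and_men(cls, total: float, men: float) -> "NationalBurden":
        """Complete the burden when only the total and the male count are
        reported: women = total - men."""
        if men > total:
            raise ValueError("male count cannot exceed the total")
        return cls(men=men, women=total - men)


def estimate_national_counts(
    source: AgeSexRateTable | dict[str, PiecewiseLogLinearFit],
    demography: Demography,
) -> NationalBurden:
    """Expected annual national fracture count: sum over bands of
    rate/100,000 x population, per sex.

    ``source`` is either a band-level rate table or per-sex smoothed fits
    (evaluated at band midpoints).
    """
    if isinstance(source, dict):
        source = smoothed_rate_table(source)
    counts = {}
    for sex in ("male", "female"):
        rates = source.rates(sex)
        pop = demography.population(sex)
        if rates.size != pop.size:
            raise ValueError("rate table and demography bands do not align")
        counts[sex] = float(np.sum(rates / RATE_DENOMINATOR * pop))
    return NationalBurden(men=counts["male"], women=counts["female"])


def impute_mof_rates(
    hip: AgeSexRateTable, ratios: dict[str, pd.DataFrame]
) -> dict[str, AgeSexRateTable]:
    """Impute non-hip major-osteoporotic-fracture rates from hip rates.

    ``ratios`` maps sex to a table (from
    :func:`fraxforge.synthetic_data.generate_ratio_table`) of site:hip
    ratios per band. Returns one rate table per site plus 'mof', the
    first-event composite whose rate is hip x (1 + sum of site ratios).
    """
    out_frames: dict[str, list[pd.DataFrame]] = {
        site: [] for site in (*MOF_SITES, "mof")
    }
    for sex in hip.sexes():
        sub = hip.frame[hip.frame["sex"] == sex].reset_index(drop=True)
        ratio = ratios[sex].reset_index(drop=True)
        merged = sub.merge(ratio, on=["sex", "age_lo", "age_hi"], how="left")
        if merged[list(MOF_SITES)].isna().any().any():
            raise KeyError(f"ratio table does not cover all bands for {sex}")
        for site in MOF_SITES:
            frame = merged[["sex", "age_lo", "age_hi"]].copy()
            frame["rate"] = merged["rate"] * merged[site]
            out_frames[site].append(frame)
        frame = merged[["sex", "age_lo", "age_hi"]].copy()
        frame["rate"] = merged["rate"] * merged["total_mof_to_hip"]
        out_frames["mof"].append(frame)
    return {
        key: AgeSexRateTable(pd.concat(frames, ignore_index=True))
        for key, frames in out_frames.items()
    }
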