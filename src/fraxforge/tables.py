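"""Core epidemiological containers: age bands, rate tables, life tables.

All incidence is carried as rates per 100,000 person-years in 5-year age
bands from 50, with a single open-ended 90+ band. Band midpoints are the
regression/interpolation abscissa; the 90+ midpoint is fixed at 92.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEXES = ("male", "female")
RATE_DENOMINATOR = 100_000.0

#: (lo, hi) half-open age bands; the last band is open (hi = inf).
AGE_BANDS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 5) if lo < 90 else np.inf) for lo in range(50, 95, 5)
)

OPEN_BAND_MIDPOINT = 92.5


def band_midpoint(lo: float, hi: float) -> float:
    return OPEN_BAND_MIDPOINT if not np.isfinite(hi) else (lo + hi) / 2.0


def band_midpoints() -> np.ndarray:
    return np.array([band_midpoint(lo, hi) for lo, hi in AGE_BANDS])


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    return sex


class AgeSexRateTable:
    """Incidence rates per 100,000 person-years by sex and 5-year age band.

    Thin wrapper over a DataFrame with columns sex, age_lo, age_hi, rate.
    """

    COLUMNS = ["sex", "age_lo", "age_hi", "rate"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"rate table missing columns {sorted(missing)}")
        frame = frame[self.COLUMNS].copy()
        if (frame["rate"] < 0).any():
            raise ValueError("rates must be non-negative")
        frame = frame.sort_values(["sex", "age_lo"], ignore_index=True)
        for sex, grp in frame.groupby("sex"):
            los, his = grp["age_lo"].to_numpy(), grp["age_hi"].to_numpy()
            if np.any(los[1:] < his[:-1]):
                raise ValueError(f"overlapping age bands for sex {sex!r}")
        self.frame = frame

    @classmethod
    def from_rates(cls, rates_by_sex: dict[str, np.ndarray]) -> "AgeSexRateTable":
        """Build from per-sex rate vectors aligned with :data:`AGE_BANDS`."""
        rows = []
        for sex, rates in rates_by_sex.items():
            _check_sex(sex)
            rates = np.asarray(rates, dtype=float)
            if rates.size != len(AGE_BANDS):
                raise ValueError(
                    f"expected {len(AGE_BANDS)} rates for {sex}, got {rates.size}"
                )
            for (lo, hi), r in zip(AGE_BANDS, rates):
                rows.append({"sex": sex, "age_lo": lo, "age_hi": hi, "rate": r})
        return cls(pd.DataFrame(rows))

    def sexes(self) -> tuple[str, ...]:
        return tuple(self.frame["sex"].unique())

    def rates(self, sex: str) -> np.ndarray:
        grp = self.frame[self.frame["sex"] == _check_sex(sex)]
        if grp.empty:
            raise KeyError(f"no rates for sex {sex!r}")
        return grp["rate"].to_numpy(dtype=float)

    def midpoints(self, sex: str) -> np.ndarray:
        grp = self.frame[self.frame["sex"] == _check_sex(sex)]
        return np.array(
            [band_midpoint(lo, hi) for lo, hi in zip(grp["age_lo"], grp["age_hi"])]
        )

    def scaled(self, factor: float) -> "AgeSexRateTable":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        out = self.frame.copy()
        out["rate"] = out["rate"] * factor
        return AgeSexRateTable(out)

    def __eq__(self, other) -> bool:
        return isinstance(other, AgeSexRateTable) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class LifeTable:
    """Annual death hazards by integer age for one sex."""

    sex: str
    ages: np.ndarray  # integer years, contiguous
    hazard: np.ndarray  # annual death hazard, > 0

    def __post_init__(self):
        _check_sex(self.sex)
        ages = np.asarray(self.ages, dtype=float)
        hazard = np.asarray(self.hazard, dtype=float)
        if ages.size != hazard.size:
            raise ValueError("ages and hazard must align")
        if np.any(hazard <= 0):
            raise ValueError("death hazards must be strictly positive")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "hazard", hazard)

    def hazard_at(self, age) -> np.ndarray:
        """Log-linear interpolation to (possibly fractional) ages."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]):
            raise ValueError(
                f"age outside life-table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        out = np.exp(np.interp(age, self.ages, np.log(self.hazard)))
        return out if age.ndim else float(out)


class Demography:
    """Population counts by sex and age band (columns region, sex, age_lo,
    age_hi, population)."""

    COLUMNS = ["region", "sex", "age_lo", "age_hi", "population"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"demography missing columns {sorted(missing)}")
        frame = frame[self.COLUMNS].copy()
        if (frame["population"] < 0).any():
            raise ValueError("population counts must be non-negative")
        self.frame = frame.sort_values(["sex", "age_lo"], ignore_index=True)

    def population(self, sex: str) -> np.ndarray:
        """Population per band (summed over regions), aligned with AGE_BANDS."""
        grp = self.frame[self.frame["sex"] == _check_sex(sex)]
        agg = grp.groupby("age_lo", sort=True)["population"].sum()
        expected = [lo for lo, _ in AGE_BANDS]
        if list(agg.index) != expected:
            raise ValueError(
                f"demography for {sex} does not cover the standard bands"
            )
        return agg.to_numpy(dtype=float)
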