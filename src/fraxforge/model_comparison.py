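"""Original-vs-updated model comparison on exhaustive clinical scenarios.

Two calibrated models are evaluated on a factorial grid of clinical risk
profiles — every combination of six dichotomous risk factors with eight
femoral-neck T-scores (0 to -3.5 SD in 0.5 SD steps) at BMI 25 kg/m^2,
i.e. 2^6 x 8 = 512 scenarios per age and sex. Agreement is summarised per
age/sex/outcome by Pearson and Spearman correlations, a continuous
two-segment regression of the updated on the original probability with a
knot at 30 percentage points, and the updated probability (with a 95%
tolerance interval from regression-residual percentiles) read at the
median of the original model's distribution.

Probabilities are proportions internally and percent in all reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from ._piecewise import ContinuousPiecewiseFit, fit_continuous_piecewise
from .probability_engine import (
    CRF_NAMES,
    REFERENCE_BMI,
    CalibratedModel,
    ten_year_probabilities,
)

DEFAULT_AGES = (50, 60, 70, 80)
#: T-scores 0 to -3.5 SD in 0.5 SD steps
TSCORE_GRID = tuple(np.arange(0.0, -4.0, -0.5))
DEFAULT_KNOT_PERCENT = 30.0
OUTCOMES = ("mof", "hip")


def build_scenario_grid(
    ages=DEFAULT_AGES,
    sexes=("male", "female"),
    bmi: float = REFERENCE_BMI,
    crf_names=CRF_NAMES,
    tscores=TSCORE_GRID,
) -> pd.DataFrame:
    """Exhaustive, duplicate-free, lexicographically ordered scenario grid.

    With the 6 standard CRFs and 8 T-scores this yields 2^6 x 8 = 512
    scenarios per (age, sex).
    """
    if len(ages) == 0:
        raise ValueError("at least one age is required")
    rows = []
    scenario_id = 0
    for age, sex in product(ages, sexes):
        for bits in range(2 ** len(crf_names)):
            for t in tscores:
                row = {
                    "scenario_id": scenario_id,
                    "age": float(age),
                    "sex": sex,
                    "bmi": float(bmi),
                    "crf_bitmask": bits,
                    "tscore": float(t),
                }
                for j, name in enumerate(crf_names):
                    row[name] = (bits >> j) & 1
                rows.append(row)
                scenario_id += 1
    grid = pd.DataFrame(rows)
    for name in CRF_NAMES:
        if name not in grid.columns:
            grid[name] = 0
    return grid


def pair_probabilities(
    model_a: CalibratedModel,
    model_b: CalibratedModel,
    grid: pd.DataFrame,
    outcome: str,
    step: str = "annual",
) -> pd.DataFrame:
    """Evaluate both models on every scenario.

    model_a plays the original (surrogate) model, model_b the update.
    Returns the grid with columns outcome, p_original, p_updated
    (proportions in [0, 1]).
    """
    out = grid.copy()
    try:
        out["p_original"] = ten_year_probabilities(model_a, grid, outcome, step)
        out["p_updated"] = ten_year_probabilities(model_b, grid, outcome, step)
    except Exception as exc:  # re-raise with scenario context
        raise RuntimeError(
            f"probability evaluation failed for outcome {outcome!r} "
            f"(scenarios {grid['scenario_id'].min()}-{grid['scenario_id'].max()})"
        ) from exc
    out["outcome"] = outcome
    return out


def agreement_stats(pairs: pd.DataFrame) -> tuple[float, float]:
    """(Pearson r, Spearman rank r) between the paired probabilities."""
    x = pairs["p_original"].to_numpy(dtype=float)
    y = pairs["p_updated"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


@dataclass(frozen=True)
class ComparisonFit:
    """Continuous piecewise-linear fit of updated on original probability,
    on the percent scale."""

    fit: ContinuousPiecewiseFit
    knot_percent: float
    single_segment: bool

    def predict_percent(self, x_percent):
        return self.fit.predict(x_percent)


def fit_comparison_regression(
    pairs: pd.DataFrame, knot: float = DEFAULT_KNOT_PERCENT
) -> ComparisonFit:
    """Two-segment least-squares regression of p_updated on p_original
    (percent scale) with a fixed knot, falling back to a single line when
    a segment holds fewer than 2 points."""
    x = pairs["p_original"].to_numpy(dtype=float) * 100.0
    y = pairs["p_updated"].to_numpy(dtype=float) * 100.0
    try:
        fit = fit_continuous_piecewise(x, y, (knot,))
        return ComparisonFit(fit=fit, knot_percent=knot, single_segment=False)
    except ValueError:
        warnings.warn(
            f"fewer than 2 points on one side of the {knot}% knot; "
            "falling back to a single straight line",
            stacklevel=2,
        )
        fit = fit_continuous_piecewise(x, y, ())
        return ComparisonFit(fit=fit, knot_percent=knot, single_segment=True)


def _normal_ti_k(n: int, coverage: float = 0.95, confidence: float = 0.95):
    """Howe's approximate two-sided normal tolerance factor."""
    z = stats.norm.ppf((1 + coverage) / 2)
    chi2 = stats.chi2.ppf(1 - confidence, n - 1)
    return z * np.sqrt((n - 1) * (1 + 1 / n) / chi2)


@dataclass(frozen=True)
class MedianComparison:
    """Updated-model probability at the median of the original model's
    distribution, with a 95% tolerance interval. Percent units."""

    median_original: float
    updated_at_median: float
    ti_lower: float
    ti_upper: float


def median_tolerance(
    pairs: pd.DataFrame,
    knot: float = DEFAULT_KNOT_PERCENT,
    method: str = "regression",
    ti_method: str = "percentile",
    min_pairs: int = 20,
    fit: ComparisonFit | None = None,
) -> MedianComparison:
    """Read the updated model at the original model's median.

    method 'regression' predicts from the comparison regression at the
    median; 'nearest' takes the paired scenario closest to the median.
    The 95% TI adds the 2.5th/97.5th percentiles of the regression
    residuals to the point estimate ('percentile'), or a normal-theory
    tolerance factor times the residual SD ('normal').
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {len(pairs)}")
    x = pairs["p_original"].to_numpy(dtype=float) * 100.0
    y = pairs["p_updated"].to_numpy(dtype=float) * 100.0
    med = float(np.median(x))
    if fit is None:
        fit = fit_comparison_regression(pairs, knot)
    if method == "regression":
        point = float(fit.predict_percent(med))
    elif method == "nearest":
        point = float(y[np.argmin(np.abs(x - med))])
    else:
        raise ValueError("method must be 'regression' or 'nearest'")
    residuals = y - fit.predict_percent(x)
    if ti_method == "percentile":
        lo_r, hi_r = np.percentile(residuals, [2.5, 97.5])
        lo, hi = point + float(lo_r), point + float(hi_r)
    elif ti_method == "normal":
        k = _normal_ti_k(len(residuals))
        sd = float(np.std(residuals, ddof=1)) if len(residuals) > 1 else 0.0
        lo, hi = point - k * sd, point + k * sd
    else:
        raise ValueError("ti_method must be 'percentile' or 'normal'")
    return MedianComparison(
        median_original=med,
        updated_at_median=point,
        ti_lower=min(lo, point),
        ti_upper=max(hi, point),
    )


def percent_reduction(comparison: MedianComparison) -> float:
    """Percent decrease of the updated relative to the original model at
    the original model's median probability."""
    if comparison.median_original == 0:
        raise ValueError("median original probability is zero")
    return (
        100.0
        * (comparison.median_original - comparison.updated_at_median)
        / comparison.median_original
    )


@dataclass(frozen=True)
class ComparisonCell:
    """Agreement summary for one (age, sex, outcome)."""

    age: float
    sex: str
    outcome: str
    n_scenarios: int
    pearson_r: float
    spearman_r: float
    median_original: float  # percent
    updated_at_median: float  # percent
    ti_lower: float
    ti_upper: float
    percent_reduction: float
    regression_coef: tuple[float, ...]
    regression_knot: float
    single_segment: bool


@dataclass(frozen=True)
class ComparisonReport:
    cells: tuple[ComparisonCell, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cells])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(c) for c in self.cells], fh, indent=1)

    def to_text(self) -> str:
        """Formatted per-age table of medians, TIs, r values and percent
        reductions, separated by outcome and sex."""
        lines = []
        frame = self.to_frame()
        for outcome in frame["outcome"].unique():
            lines.append(f"10-year probability (%), outcome: {outcome.upper()}")
            header = (
                f"{'Age':>4} {'Sex':>7} {'Original':>9} {'Update':>7} "
                f"{'95% TI':>12} {'r':>6} {'Reduction':>10}"
            )
            lines.append(header)
            sub = frame[frame["outcome"] == outcome]
            for _, row in sub.iterrows():
                lines.append(
                    f"{row['age']:>4.0f} {row['sex']:>7} "
                    f"{row['median_original']:>9.1f} "
                    f"{row['updated_at_median']:>7.1f} "
                    f"{row['ti_lower']:>5.1f}-{row['ti_upper']:<6.1f} "
                    f"{row['pearson_r']:>6.3f} "
                    f"{row['percent_reduction']:>9.1f}%"
                )
            lines.append("")
        return "\n".join(lines)


def compare_models(
    model_original: CalibratedModel,
    model_updated: CalibratedModel,
    ages=DEFAULT_AGES,
    sexes=("male", "female"),
    outcomes=OUTCOMES,
    knot: float = DEFAULT_KNOT_PERCENT,
    step: str = "annual",
    ti_method: str = "percentile",
) -> tuple[ComparisonReport, pd.DataFrame]:
    """Full comparison: per (age, sex, outcome) cell statistics plus the
    concatenated paired-probability table."""
    cells = []
    all_pairs = []
    for outcome in outcomes:
        for sex in sexes:
            for age in ages:
                grid = build_scenario_grid(ages=(age,), sexes=(sex,))
                pairs = pair_probabilities(
                    model_original, model_updated, grid, outcome, step
                )
                all_pairs.append(pairs)
                pearson, spearman = agreement_stats(pairs)
                reg = fit_comparison_regression(pairs, knot)
                comp = median_tolerance(
                    pairs, knot=knot, ti_method=ti_method, fit=reg
                )
                cells.append(
                    ComparisonCell(
                        age=float(age),
                        sex=sex,
                        outcome=outcome,
                        n_scenarios=len(pairs),
                        pearson_r=pearson,
                        spearman_r=spearman,
                        median_original=comp.median_original,
                        updated_at_median=comp.updated_at_median,
                        ti_lower=comp.ti_lower,
                        ti_upper=comp.ti_upper,
                        percent_reduction=percent_reduction(comp),
                        regression_coef=reg.fit.coef,
                        regression_knot=knot,
                        single_segment=reg.single_segment,
                    )
                )
    report = ComparisonReport(cells=tuple(cells))
    return report, pd.concat(all_pairs, ignore_index=True)


def plot_pairs(pairs: pd.DataFrame, path, title: str | None = None) -> None:
    """Scatter of updated vs original probabilities with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    x = pairs["p_original"] * 100.0
    y = pairs["p_updated"] * 100.0
    ax.scatter(x, y, s=6, alpha=0.4)
    lim = max(x.max(), y.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k-", lw=1)
    ax.set_xlabel("Original model 10-year probability (%)")
    ax.set_ylabel("Updated model 10-year probability (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
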