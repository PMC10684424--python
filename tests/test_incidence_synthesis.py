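"""Region weighting, segmented log-linear smoothing, national burden, and
MOF imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fraxforge._piecewise import ContinuousPiecewiseFit, fit_continuous_piecewise
from fraxforge.incidence_synthesis import (
    DEFAULT_BREAKPOINTS,
    NationalBurden,
    PiecewiseLogLinearFit,
    RegionWeights,
    combine_regions,
    estimate_national_counts,
    fit_piecewise_loglinear,
    impute_mof_rates,
    predict_rate,
)
from fraxforge.synthetic_data import (
    MOF_SITES,
    CityIncidenceSample,
    generate_demography,
    generate_ratio_table,
)
from fraxforge.tables import AGE_BANDS, AgeSexRateTable, Demography, band_midpoints

from helpers import flat_rate_table


def city_samples(city, region, rates_per_band, person_years=100_000.0):
    """One sex ('female') of band samples with exact rates."""
    out = []
    for (lo, hi), rate in zip(AGE_BANDS, rates_per_band):
        out.append(
            CityIncidenceSample(
                city_name=city,
                region=region,
                sex="female",
                age_lo=lo,
                age_hi=hi,
                fracture_count=int(round(rate / 1e5 * person_years)),
                person_years=person_years,
            )
        )
    return out


class TestCombineRegions:
    def test_identical_rates_are_a_fixed_point(self):
        rates = np.full(len(AGE_BANDS), 150.0)
        samples = city_samples("A", "R1", rates) + city_samples("B", "R2", rates)
        combined = combine_regions(samples, RegionWeights({"R1": 0.3, "R2": 0.7}))
        assert np.allclose(combined.rates("female"), 150.0)

    def test_two_city_weighted_mean(self):
        samples = city_samples("A", "R1", np.full(9, 100.0)) + city_samples(
            "B", "R2", np.full(9, 200.0)
        )
        combined = combine_regions(samples, RegionWeights({"R1": 0.75, "R2": 0.25}))
        assert np.allclose(combined.rates("female"), 125.0)

    def test_unnormalised_population_shares_are_renormalised(self):
        # shares 0.42/0.28/0.14 (84% of the population) act as 0.5/1/3 etc.
        samples = (
            city_samples("SE", "Southeast", np.full(9, 100.0))
            + city_samples("NE", "Northeast", np.full(9, 200.0))
            + city_samples("S", "South", np.full(9, 300.0))
        )
        weights = RegionWeights({"Southeast": 0.42, "Northeast": 0.28, "South": 0.14})
        combined = combine_regions(samples, weights)
        expected = (0.42 * 100 + 0.28 * 200 + 0.14 * 300) / 0.84
        assert np.allclose(combined.rates("female"), expected)

    def test_two_cities_in_one_region_rejected(self):
        samples = city_samples("A", "R1", np.full(9, 100.0)) + city_samples(
            "B", "R1", np.full(9, 200.0)
        )
        with pytest.raises(ValueError, match="exactly one city"):
            combine_regions(samples, RegionWeights({"R1": 1.0}))

    def test_band_mismatch_rejected(self):
        samples = city_samples("A", "R1", np.full(9, 100.0)) + city_samples(
            "B", "R2", np.full(9, 200.0)
        )
        samples = [s for s in samples if not (s.city_name == "B" and s.age_lo == 70)]
        with pytest.raises(ValueError, match="band"):
            combine_regions(samples, RegionWeights({"R1": 0.5, "R2": 0.5}))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        r1=st.floats(10.0, 500.0),
        r2=st.floats(10.0, 500.0),
        w1=st.floats(0.05, 0.95),
    )
    def test_convex_combination_bounded_by_city_rates(self, r1, r2, w1):
        samples = city_samples("A", "R1", np.full(9, r1)) + city_samples(
            "B", "R2", np.full(9, r2)
        )
        combined = combine_regions(
            samples, RegionWeights({"R1": w1, "R2": 1.0 - w1})
        )
        # counts are rounded to integers, so allow a half-count of slack
        lo = min(r1, r2) - 0.5
        hi = max(r1, r2) + 0.5
        assert np.all(combined.rates("female") >= lo)
        assert np.all(combined.rates("female") <= hi)


def rates_from_segments(ages, intercept, slopes, knots):
    """Independent evaluation of a continuous segmented line."""
    out = []
    for a in ages:
        y = intercept
        prev = 50.0
        for seg, (k_lo, k_hi) in enumerate(
            zip((50.0, *knots), (*knots, np.inf))
        ):
            if a > k_hi:
                y += slopes[seg] * (k_hi - k_lo)
            else:
                y += slopes[seg] * (a - k_lo)
                break
        out.append(y)
    return np.array(out)


class TestPiecewiseFit:
    def test_collinear_data_recovers_single_slope(self):
        mids = band_midpoints()
        log_rates = 1.0 + 0.08 * mids
        table = AgeSexRateTable.from_rates(
            {"male": np.exp(log_rates), "female": np.exp(log_rates)}
        )
        fit = fit_piecewise_loglinear(table, (62.0, 87.0), "male")
        assert np.allclose(fit.segment_slopes, 0.08, atol=1e-8)

    def test_two_segment_truth_recovered_exactly(self):
        mids = band_midpoints()
        log_rates = rates_from_segments(mids, np.log(30.0), (0.05, 0.11), (62.0,))
        table = AgeSexRateTable.from_rates(
            {"female": np.exp(log_rates), "male": np.exp(log_rates)}
        )
        fit = fit_piecewise_loglinear(table, (62.0,), "female")
        assert fit.segment_slopes == pytest.approx((0.05, 0.11), abs=1e-6)

    def test_default_breakpoints(self):
        assert DEFAULT_BREAKPOINTS["male"] == (62.0, 87.0)
        assert DEFAULT_BREAKPOINTS["female"] == (62.0, 82.0)

    def test_continuity_at_breakpoints(self):
        rng = np.random.default_rng(4)
        mids = band_midpoints()
        rates = np.exp(1.0 + 0.07 * mids + rng.normal(0, 0.2, mids.size))
        table = AgeSexRateTable.from_rates({"male": rates, "female": rates})
        fit = fit_piecewise_loglinear(table, (62.0, 87.0), "male")
        assert np.allclose(fit.continuity_residuals(), 0.0, atol=1e-9)
        for knot in fit.breakpoints:
            left = predict_rate(fit, knot - 1e-9)
            right = predict_rate(fit, knot + 1e-9)
            assert left == pytest.approx(right, rel=1e-6)

    def test_adding_knots_never_increases_rss(self):
        rng = np.random.default_rng(8)
        mids = band_midpoints()
        y = 1.0 + 0.07 * mids + rng.normal(0, 0.3, mids.size)
        single = fit_continuous_piecewise(mids, y, ())
        kinked = fit_continuous_piecewise(mids, y, (62.0, 82.0))
        assert kinked.rss <= single.rss + 1e-12

    def test_zero_rate_band_excluded_by_default(self):
        mids = band_midpoints()
        rates = np.exp(1.0 + 0.07 * mids)
        rates[3] = 0.0
        table = AgeSexRateTable.from_rates({"male": rates, "female": rates})
        fit = fit_piecewise_loglinear(table, (62.0, 87.0), "male")
        assert np.allclose(fit.segment_slopes, 0.07, atol=1e-8)

    def test_slopes_consistent_under_poisson_noise_at_high_exposure(self):
        """With ample exposure (8e6 person-years/band, three cities) the
        segmented fit recovers the generating slopes within 10% relative
        in every one of 20 replicates: the estimator is consistent and
        recovery error is purely sampling noise."""
        from fraxforge.synthetic_data import (
            GroundTruthIncidence,
            generate_city_incidence,
        )

        truth = GroundTruthIncidence.default()
        cities = [
            ("Belem", "Northeast", 0.6),
            ("Vitoria", "Southeast", 1.0),
            ("Joinville", "South", 1.4),
        ]
        weights = RegionWeights(
            {"Southeast": 0.42, "Northeast": 0.28, "South": 0.14}
        )
        for rep in range(20):
            samples = generate_city_incidence(
                truth, cities, 8_000_000.0, seed=40_000 + rep
            )
            table = combine_regions(samples, weights)
            for sex, sex_truth in (
                ("male", truth.male),
                ("female", truth.female),
            ):
                fit = fit_piecewise_loglinear(table, sex_truth.breakpoints, sex)
                rel = np.abs(
                    np.asarray(fit.segment_slopes) - np.asarray(sex_truth.slopes)
                ) / np.asarray(sex_truth.slopes)
                assert np.all(rel < 0.10)

    def test_too_few_points_per_segment_rejected(self):
        mids = band_midpoints()
        rates = np.exp(1.0 + 0.07 * mids)
        table = AgeSexRateTable.from_rates({"male": rates, "female": rates})
        with pytest.raises(ValueError, match="segment"):
            fit_piecewise_loglinear(table, (89.0,), "male")


class TestPredictRate:
    def make_flat_fit(self, level=np.log(100.0)):
        fit = ContinuousPiecewiseFit(
            knots=(62.0, 87.0), coef=(level, 0.0, 0.0, 0.0), rss=0.0, n_points=9
        )
        return PiecewiseLogLinearFit(sex="male", fit=fit)

    def test_flat_fit_predicts_constant(self):
        fit = self.make_flat_fit()
        for age in (50.0, 62.0, 75.0, 110.0):
            assert predict_rate(fit, age) == pytest.approx(100.0)

    def test_closed_form_prediction(self):
        a, b = -2.0, 0.09
        fit = PiecewiseLogLinearFit(
            sex="female",
            fit=ContinuousPiecewiseFit(
                knots=(82.0,), coef=(a, b, 0.0), rss=0.0, n_points=9
            ),
        )
        assert predict_rate(fit, 70.0) == pytest.approx(np.exp(a + 70.0 * b))

    def test_age_outside_range_rejected(self):
        fit = self.make_flat_fit()
        for age in (49.9, 110.1):
            with pytest.raises(ValueError, match="age"):
                predict_rate(fit, age)


class TestNationalBurden:
    def one_band_demography(self, band_index, population):
        rows = []
        for i, (lo, hi) in enumerate(AGE_BANDS):
            for sex in ("male", "female"):
                rows.append(
                    {
                        "region": "National",
                        "sex": sex,
                        "age_lo": lo,
                        "age_hi": hi,
                        "population": population if i == band_index else 0,
                    }
                )
        return Demography(pd.DataFrame(rows))

    def test_zero_rates_give_zero_burden(self):
        burden = estimate_national_counts(
            flat_rate_table(0.0), generate_demography(1_000_000)
        )
        assert burden.total == 0.0

    def test_single_band_hand_arithmetic(self):
        # 200/100,000 x 50,000 people = 100 expected fractures per sex
        table = flat_rate_table(200.0)
        demog = self.one_band_demography(band_index=2, population=50_000)
        burden = estimate_national_counts(table, demog)
        assert burden.men == pytest.approx(100.0)
        assert burden.women == pytest.approx(100.0)

    def test_linear_in_rate_and_population(self):
        demog = generate_demography(2_000_000)
        b1 = estimate_national_counts(flat_rate_table(100.0), demog)
        b2 = estimate_national_counts(flat_rate_table(300.0), demog)
        assert b2.total == pytest.approx(3.0 * b1.total)
        demog2 = generate_demography(4_000_000)
        b3 = estimate_national_counts(flat_rate_table(100.0), demog2)
        assert b3.total == pytest.approx(2.0 * b1.total, rel=1e-3)

    def test_women_complete_the_reported_total(self):
        burden = NationalBurden.from_total_and_men(total=56_526, men=19_555)
        assert burden.women == 36_971
        assert round(100 * burden.male_share) == 35


class TestImputeMof:
    @staticmethod
    def unit_ratio_tables():
        out = {}
        for sex in ("male", "female"):
            table = generate_ratio_table(sex).copy()
            for site in MOF_SITES:
                table[site] = 1.0
            table["total_mof_to_hip"] = 4.0
            out[sex] = table
        return out

    def test_unit_ratios_reproduce_hip_rates(self):
        hip = flat_rate_table(150.0)
        imputed = impute_mof_rates(hip, self.unit_ratio_tables())
        for site in MOF_SITES:
            assert np.allclose(imputed[site].rates("female"), 150.0)
        assert np.allclose(imputed["mof"].rates("female"), 4 * 150.0)

    def test_site_rate_is_hip_times_ratio(self):
        hip = flat_rate_table(150.0)
        ratios = self.unit_ratio_tables()
        ratios["female"]["forearm"] = 2.2
        imputed = impute_mof_rates(hip, ratios)
        assert np.allclose(imputed["forearm"].rates("female"), 330.0)
        assert np.allclose(imputed["forearm"].rates("male"), 150.0)

    def test_zero_hip_rate_propagates(self):
        hip = flat_rate_table(0.0)
        imputed = impute_mof_rates(hip, self.unit_ratio_tables())
        for key in (*MOF_SITES, "mof"):
            assert np.allclose(imputed[key].rates("male"), 0.0)

    def test_missing_band_in_ratio_table_rejected(self):
        hip = flat_rate_table(100.0)
        ratios = self.unit_ratio_tables()
        ratios["male"] = ratios["male"].iloc[:-1]
        with pytest.raises(KeyError, match="cover"):
            impute_mof_rates(hip, ratios)

    def test_generated_ratios_keep_mof_above_hip(self):
        hip = flat_rate_table(100.0)
        ratios = {sex: generate_ratio_table(sex) for sex in ("male", "female")}
        imputed = impute_mof_rates(hip, ratios)
        for sex in ("male", "female"):
            assert np.all(imputed["mof"].rates(sex) > hip.rates(sex))
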