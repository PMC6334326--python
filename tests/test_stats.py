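"""Validation statistics: calibration fit, lack-of-fit ANOVA, LOD/LOQ,
precision, content, recovery, SST summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import cevalid as cv
from cevalid.peaks import Peak
from cevalid.reference import REFERENCE_SST, reference_calibration_dataset


def balanced_dataset(seed: int, k: int, r: int) -> cv.CalibrationDataset:
    rng = np.random.default_rng(seed)
    levels = np.arange(1, k + 1) * 10.0
    areas = [100.0 + 5.0 * c + rng.normal(0, 3.0, r) for c in levels]
    return cv.CalibrationDataset(levels=levels, areas=areas)


class TestFitCalibration:
    def test_exact_line_recovered(self):
        x = np.repeat([70, 80, 90, 100, 110, 120], 3).astype(float)
        y = 2281.7 * x - 24495
        fit = cv.fit_calibration(cv.CalibrationDataset.from_points(x, y))
        assert fit.slope == pytest.approx(2281.7)
        assert fit.intercept == pytest.approx(-24495)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_response_has_zero_slope(self):
        fit = cv.fit_calibration(
            cv.CalibrationDataset.from_points([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        )
        assert fit.slope == pytest.approx(0.0)

    def test_simple_proportional_line(self):
        fit = cv.fit_calibration(cv.CalibrationDataset.from_points([1, 2, 3], [2, 4, 6]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            cv.fit_calibration(cv.CalibrationDataset.from_points([1, 1, 2], [1, 2, 3]))


class TestLinearityAnova:
    def test_df_column_for_six_levels_triplicate(self):
        part = cv.linearity_anova(balanced_dataset(0, 6, 3))
        assert [r.df for r in part.rows] == [5, 1, 4, 12, 17]

    def test_reference_partition_reproduces_published_table(self):
        # six-level triplicate replica constructed from the reference SS
        part = cv.linearity_anova(reference_calibration_dataset())
        assert round(part.row("residue").ms, 2) == 2744346.59
        assert round(part.row("between-concentration").f, 2) == 1993.04
        assert round(part.row("linear regression").f, 2) == 9953.42
        assert round(part.row("deviation of linearity").f, 2) == 2.95
        assert part.row("total").ss == pytest.approx(27380932319.19, abs=0.01)
        assert part.row("deviation of linearity").significant is False

    def test_noiseless_linear_data_has_zero_lack_of_fit(self):
        levels = np.array([70.0, 80, 90, 100, 110, 120])
        data = cv.CalibrationDataset(
            levels=levels, areas=[np.full(3, 2281.7 * c - 24495) for c in levels]
        )
        part = cv.linearity_anova(data)
        total = part.row("total").ss
        assert part.row("deviation of linearity").ss == pytest.approx(0.0, abs=1e-6 * total)
        assert part.row("residue").ss == pytest.approx(0.0, abs=1e-6 * total)

    def test_unequal_replicates_rejected_with_fit_hint(self):
        data = cv.CalibrationDataset(
            levels=np.array([1.0, 2.0, 3.0]),
            areas=[np.array([1.0, 2.0]), np.array([2.0]), np.array([3.0, 4.0])],
        )
        with pytest.raises(ValueError, match="fit_calibration"):
            cv.linearity_anova(data)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        k=st.integers(3, 6),
        r=st.integers(2, 4),
    )
    def test_additivity_and_brute_force_oracle(self, seed, k, r):
        data = balanced_dataset(seed, k, r)
        part = cv.linearity_anova(data)
        # df and SS additivity
        assert part.row("between-concentration").df + part.row("residue").df == part.row("total").df
        tot = part.row("total").ss
        assert part.row("between-concentration").ss + part.row("residue").ss == pytest.approx(
            tot, rel=1e-6
        )
        assert part.row("linear regression").ss + part.row(
            "deviation of linearity"
        ).ss == pytest.approx(part.row("between-concentration").ss, rel=1e-6)
        # brute-force double-loop oracle for SS_total and SS_between
        ys = [y for a in data.areas for y in a]
        grand = sum(ys) / len(ys)
        ss_total_bf = sum((y - grand) ** 2 for y in ys)
        ss_between_bf = sum(
            len(a) * (sum(a) / len(a) - grand) ** 2 for a in data.areas
        )
        assert part.row("total").ss == pytest.approx(ss_total_bf, rel=1e-9)
        assert part.row("between-concentration").ss == pytest.approx(ss_between_bf, rel=1e-9)
        # F for regression equals the squared t of the slope
        x, y = data.points()
        lr = sps.linregress(x, y)
        t_sq = (lr.slope / lr.stderr) ** 2
        # same statistic only when lack of fit is pooled; compare against
        # the regression F recomputed with the pooled residual MS
        ss_pooled = part.row("deviation of linearity").ss + part.row("residue").ss
        ms_pooled = ss_pooled / (part.row("deviation of linearity").df + part.row("residue").df)
        f_pooled = part.row("linear regression").ms / ms_pooled
        assert f_pooled == pytest.approx(t_sq, rel=1e-6)


class TestFCritical:
    @pytest.mark.parametrize(
        "df1,expected", [(5, 3.11), (1, 4.75), (4, 3.26)]
    )
    def test_published_quantiles(self, df1, expected):
        assert round(cv.f_critical(0.05, df1, 12), 2) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cv.f_critical(0.05, 0, 12)
        with pytest.raises(ValueError):
            cv.f_critical(1.5, 1, 12)


class TestLodLoq:
    def test_zero_sigma_gives_zero_limits(self):
        res = cv.lod_loq(0.0, 2281.7)
        assert res.lod == 0.0 and res.loq == 0.0

    def test_ratio_identity(self):
        res = cv.lod_loq(123.4, 987.6)
        assert res.loq / res.lod == pytest.approx(10.0 / 3.0)

    def test_direct_arithmetic(self):
        assert cv.lod_loq(228.17, 2281.7).lod == pytest.approx(0.3)

    def test_non_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            cv.lod_loq(1.0, 0.0)


class TestRsd:
    def test_constant_series_has_zero_rsd(self):
        assert cv.rsd([7.0, 7.0, 7.0]).rsd_percent == 0.0

    def test_hand_computed_example(self):
        res = cv.rsd([1.0, 2.0, 3.0])
        assert res.mean == 2.0 and res.sd == pytest.approx(1.0)
        assert res.rsd_percent == pytest.approx(50.0)

    def test_reference_migration_times(self):
        times = [row[1] for row in REFERENCE_SST]
        assert round(cv.rsd(times).sd, 2) == 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cv.rsd([1.0])
        with pytest.raises(ValueError):
            cv.rsd([-1.0, 1.0])


class TestContentAndRecovery:
    def test_identity_content(self):
        assert cv.assay_content(100.0, 100.0, 50.0, 50.0).cs_percent == pytest.approx(100.0)

    def test_zero_sample_area(self):
        res = cv.assay_content(0.0, 100.0, 50.0, 50.0)
        assert res.cs == 0.0 and res.cs_percent == 0.0

    def test_headline_content_scale(self):
        res = cv.assay_content(0.9994 * 203675, 203675, 100.0, 100.0)
        assert res.cs_percent == pytest.approx(99.94)

    def test_invalid_content_inputs(self):
        with pytest.raises(ValueError):
            cv.assay_content(1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            cv.assay_content(1.0, 1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "cf,cu,ca,expected",
        [(80.0, 70.0, 10.0, 100.0), (75.0, 70.0, 10.0, 50.0), (70.0, 70.0, 10.0, 0.0)],
    )
    def test_recovery_arithmetic(self, cf, cu, ca, expected):
        assert cv.recovery(cf, cu, ca).r_percent == pytest.approx(expected)

    def test_recovery_requires_positive_spike(self):
        with pytest.raises(ValueError):
            cv.recovery(80.0, 70.0, 0.0)


def _peak(area=200000.0, t=3.2, n=11000.0, asym=0.84) -> Peak:
    return Peak(
        apex_time=t, height=10.0, raw_area=area * t, corrected_area=area,
        width_half_height=0.07, plate_number=n, asymmetry=asym,
        start_time=t - 0.2, end_time=t + 0.2,
    )


class TestSstSummary:
    def test_identical_peaks_all_pass(self):
        table = cv.sst_summary([_peak() for _ in range(10)], rsd_limit=2.0)
        assert len(table) == 4
        assert np.allclose(table["rsd_percent"], 0.0, atol=1e-9)
        assert table["passed"].all()

    def test_metric_over_limit_fails(self):
        peaks = [_peak(area=200000.0 * (1 + 0.05 * (-1) ** i)) for i in range(10)]
        table = cv.sst_summary(peaks, rsd_limit=2.0).set_index("metric")
        assert not table.loc["corrected_area", "passed"]
        assert table.loc["apex_time", "passed"]

    def test_simulated_sst_study_produces_finite_table(self):
        runs = cv.simulate_sst_study(cv.SimulationConfig(seed=21), n=10)
        peaks = [cv.measure_run(eg, 1.0) for eg in runs]
        table = cv.sst_summary(peaks, rsd_limit=2.0)
        assert list(table["metric"]) == [
            "corrected_area", "apex_time", "plate_number", "asymmetry",
        ]
        assert np.isfinite(table["rsd_percent"]).all()

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValueError):
            cv.sst_summary([_peak()])


class TestIntermediatePrecision:
    def test_equal_day_means(self):
        assert cv.intermediate_precision([100.0, 100.0]).rsd_percent == 0.0

    def test_two_day_hand_computation(self):
        res = cv.intermediate_precision([99.0, 101.0])
        assert res.mean == 100.0
        assert res.rsd_percent == pytest.approx(100 * np.sqrt(2) / 100.0, rel=1e-6)

    def test_three_day_series(self):
        res = cv.intermediate_precision([102.84, 99.83, 99.15])
        assert round(res.rsd_percent, 2) == 1.95

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            cv.intermediate_precision([100.0])
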