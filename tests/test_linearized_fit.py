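"""The time-eliminated SGR-vs-ln(volume) regression estimator."""

import math

import numpy as np
import pytest

from metagrowth import (
    DataError,
    GENERAL_GOMPERTZ,
    GrowthParameters,
    HETEROGENEOUS_EXPONENTIAL,
    IntervalEstimate,
    LesionSeries,
    describe_heterogeneous,
    fit_sgr_logv,
    series_to_intervals,
    volume_at,
)


def _records(xs, ys, lesion_id="L"):
    return [
        IntervalEstimate(lesion_id, sgr=float(y), log_gm_volume=float(x), t_mid=0.0, t1=0.0, t2=1.0)
        for x, y in zip(xs, ys)
    ]


def ols_oracle(x, y):
    """Closed-form normal equations: independent cross-check of the fit."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestFitSgrLogV:
    def test_worked_example_recovers_generating_parameters(self, appendix_lesion):
        """OLS over the 20 interval records of the worked example returns
        the generating SGR0 = 0.001/day and lam = 0.0003/day within 1%."""
        ivs = series_to_intervals(appendix_lesion)
        fit = fit_sgr_logv(ivs, v0_assumed=1.0)
        assert fit.n_points == 20
        assert fit.lam == pytest.approx(0.0003, rel=0.01)
        assert fit.sgr0 == pytest.approx(0.001, rel=0.01)
        assert fit.selected_model == GENERAL_GOMPERTZ

    def test_exact_linear_data(self):
        xs = [0.0, 1.0, 2.0]
        ys = [0.002 - 0.0001 * x for x in xs]
        fit = fit_sgr_logv(_records(xs, ys), v0_assumed=1.0)
        assert fit.sgr0 == pytest.approx(0.002, rel=1e-12)
        assert fit.lam == pytest.approx(0.0001, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle_on_random_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.normal(0.0, 2.0, n)
            if np.ptp(x) == 0.0:
                continue
            y = rng.normal(0.001, 0.0005, n)
            fit = fit_sgr_logv(_records(x, y), v0_assumed=1.0)
            slope, intercept = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_scale_equivariance(self):
        """Multiplying all volumes by c leaves the slope (hence lam)
        unchanged and shifts the intercept by -slope*ln(c)."""
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.5, 20)
        y = 0.003 - 0.0002 * x + rng.normal(0, 1e-4, 20)
        c = 7.5
        base = fit_sgr_logv(_records(x, y), v0_assumed=1.0)
        scaled = fit_sgr_logv(_records(x + math.log(c), y), v0_assumed=1.0)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(base.intercept - base.slope * math.log(c), rel=1e-10)
        # quoting SGR0 at a c-scaled reference volume undoes the shift
        rescaled = fit_sgr_logv(_records(x + math.log(c), y), v0_assumed=c)
        assert rescaled.sgr0 == pytest.approx(base.sgr0, rel=1e-10)

    def test_record_order_irrelevant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.001, 3e-4, 15)
        recs = _records(x, y)
        a = fit_sgr_logv(recs, v0_assumed=1.0)
        b = fit_sgr_logv(list(reversed(recs)), v0_assumed=1.0)
        assert a.slope == pytest.approx(b.slope, rel=1e-14)
        assert a.r2 == pytest.approx(b.r2, rel=1e-14)

    def test_noiseless_parameter_recovery_small_lambda_dt(self, make_gompertz_series):
        """Any Gompertz truth with lam*dt <= 0.1 is recovered within 1%."""
        for lam, dt in [(0.0005, 200.0), (0.001, 100.0), (0.0001, 1000.0)]:
            p = GrowthParameters(sgr0=0.004, lam=lam, v0=1.0, t0=0.0)
            s = make_gompertz_series(p, np.arange(0.0, 12.1 * dt, dt))
            fit = fit_sgr_logv(series_to_intervals(s), v0_assumed=1.0)
            assert fit.lam == pytest.approx(lam, rel=0.01)
            assert fit.sgr0 == pytest.approx(0.004, rel=0.01)

    def test_nonnegative_slope_reports_lam_zero_with_flag(self):
        xs = [0.0, 1.0, 2.0, 3.0]
        ys = [0.001, 0.0012, 0.0014, 0.0016]
        fit = fit_sgr_logv(_records(xs, ys), v0_assumed=1.0)
        assert fit.slope > 0
        assert fit.lam == 0.0
        assert fit.slope_nonnegative
        assert fit.selected_model == HETEROGENEOUS_EXPONENTIAL

    def test_insignificant_negative_slope_selects_heterogeneous(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.002, 0.002, 10) - 1e-6 * x
        fit = fit_sgr_logv(_records(x, y), v0_assumed=1.0)
        if fit.p_slope >= fit.alpha:
            assert fit.selected_model == HETEROGENEOUS_EXPONENTIAL

    def test_too_few_records(self):
        with pytest.raises(DataError):
            fit_sgr_logv(_records([0, 1], [0.001, 0.002]))

    def test_degenerate_design(self):
        with pytest.raises(DataError):
            fit_sgr_logv(_records([1.0, 1.0, 1.0], [0.001, 0.002, 0.003]))


class TestDescribeHeterogeneous:
    def test_single_interval(self):
        summ = describe_heterogeneous(_records([0.5], [0.0023]))
        assert summ.lesions[0].mean_sgr == pytest.approx(0.0023)
        assert summ.sgr_min == summ.sgr_max == pytest.approx(0.0023)

    def test_time_weighted_mean(self):
        recs = [
            IntervalEstimate("a", sgr=0.001, log_gm_volume=0.0, t_mid=50, t1=0, t2=100),
            IntervalEstimate("a", sgr=0.003, log_gm_volume=0.5, t_mid=250, t1=100, t2=400),
        ]
        summ = describe_heterogeneous(recs)
        assert summ.lesions[0].mean_sgr == pytest.approx(0.0025)

    def test_recovers_generator_rates_noiselessly(self, make_gompertz_series):
        """Exponential lesions with distinct rates are recovered exactly
        from noiseless data."""
        truth = {"a": 0.0014, "b": 0.0022, "c": 0.0039}
        recs = []
        for lid, sgr in truth.items():
            p = GrowthParameters(sgr0=sgr, lam=0.0, v0=1.0, t0=0.0)
            recs += series_to_intervals(
                make_gompertz_series(p, np.arange(0, 1500.0, 300.0), lesion_id=lid)
            )
        summ = describe_heterogeneous(recs)
        for lesion in summ.lesions:
            assert lesion.mean_sgr == pytest.approx(truth[lesion.lesion_id], rel=1e-12)
        assert summ.sgr_min == pytest.approx(0.0014)
        assert summ.sgr_max == pytest.approx(0.0039)
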