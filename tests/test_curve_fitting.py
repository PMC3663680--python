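"""Direct per-lesion exponential and Gompertz fits."""

import math

import numpy as np
import pytest

from metagrowth import (
    DataError,
    FitError,
    GrowthParameters,
    LesionSeries,
    compare_models,
    fit_exponential,
    fit_gompertz,
    interval_sgr,
    volume_at,
)


class TestFitExponential:
    def test_noiseless_recovery_is_exact(self, make_gompertz_series):
        p = GrowthParameters(sgr0=0.002, lam=0.0, v0=5.0, t0=0.0)
        fit = fit_exponential(make_gompertz_series(p, [0, 200, 400, 800.0]))
        assert fit.params.sgr0 == pytest.approx(0.002, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_equal_interval_sgr(self):
        s = LesionSeries.from_arrays("x", [10.0, 110.0], [1.0, 1.8])
        fit = fit_exponential(s)
        assert fit.params.sgr0 == pytest.approx(interval_sgr(1.0, 1.8, 10.0, 110.0), rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_formation_time_back_extrapolates_to_one_cell(self, make_gompertz_series):
        """A lesion grown from one cell at t=0 is dated to t=0."""
        p = GrowthParameters(sgr0=0.002, lam=0.0, v0=1e-9, t0=0.0)
        s = make_gompertz_series(p, [9000.0, 9180.0, 9360.0])
        fit = fit_exponential(s)
        assert fit.formation_time == pytest.approx(0.0, abs=1e-6)

    def test_shrinking_lesion_has_no_formation_time(self):
        s = LesionSeries.from_arrays("x", [0.0, 100.0], [2.0, 1.5])
        fit = fit_exponential(s)
        assert math.isnan(fit.formation_time)

    def test_single_point_rejected(self):
        with pytest.raises(FitError):
            fit_exponential(LesionSeries.from_arrays("x", [0.0], [1.0]))


class TestFitGompertz:
    def test_noiseless_recovery(self, appendix_params, make_gompertz_series):
        s = make_gompertz_series(appendix_params, [0.0, 900.0, 1800.0, 3600.0])
        fit = fit_gompertz(s, one_cell_volume=1e-9)
        assert fit.params.lam == pytest.approx(appendix_params.lam, rel=1e-3)
        assert fit.params.sgr0 == pytest.approx(appendix_params.sgr0, rel=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_exponential_data_hits_lambda_zero_boundary(self, make_gompertz_series):
        p = GrowthParameters(sgr0=0.0015, lam=0.0, v0=2.0, t0=0.0)
        s = make_gompertz_series(p, [0, 300, 600, 900.0])
        gom = fit_gompertz(s)
        exp = fit_exponential(s)
        assert gom.params.lam == 0.0
        assert gom.params.sgr0 == pytest.approx(exp.params.sgr0, abs=1e-8)
        assert gom.sse <= exp.sse + 1e-10

    def test_two_points_rejected(self):
        s = LesionSeries.from_arrays("x", [0.0, 100.0], [1.0, 2.0])
        with pytest.raises(FitError):
            fit_gompertz(s)

    def test_sgr_at_formation_uses_one_cell_convention(self, make_gompertz_series):
        """The reported SGR0 is the rate the fitted curve had at the
        one-cell volume, not at the first measurement."""
        p = GrowthParameters(sgr0=0.008, lam=0.00025, v0=1e-9, t0=0.0)
        s = make_gompertz_series(p, [5000.0, 5360.0, 5720.0, 6080.0])
        fit = fit_gompertz(s, one_cell_volume=1e-9)
        assert fit.sgr_at_formation == pytest.approx(0.008, rel=1e-3)
        assert fit.formation_time == pytest.approx(0.0, abs=2.0)

    @pytest.mark.parametrize("n_points", [3, 4, 6])
    def test_nesting_gompertz_sse_never_worse(self, n_points):
        """lam = 0 is feasible, so the Gompertz SSE cannot exceed the
        exponential SSE on any series."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = np.sort(rng.uniform(0, 2000, n_points))
            t += np.arange(n_points)  # ensure strictly increasing
            v = np.exp(rng.normal(0.0, 1.0, n_points))
            s = LesionSeries.from_arrays("x", t, v)
            assert fit_gompertz(s).sse <= fit_exponential(s).sse + 1e-10

    def test_time_translation_equivariance(self, appendix_params, make_gompertz_series):
        times = np.array([0.0, 600.0, 1200.0, 2400.0])
        s0 = make_gompertz_series(appendix_params, times)
        shifted = LesionSeries.from_arrays("L", times + 500.0, s0.volumes)
        f0, f1 = fit_gompertz(s0), fit_gompertz(shifted)
        assert f1.formation_time - f0.formation_time == pytest.approx(500.0, abs=1e-6)

    def test_volume_unit_equivariance(self, appendix_params, make_gompertz_series):
        times = np.array([0.0, 600.0, 1200.0, 2400.0])
        s0 = make_gompertz_series(appendix_params, times)
        c = 1000.0
        scaled = LesionSeries.from_arrays("L", times, s0.volumes * c)
        f0, f1 = fit_gompertz(s0), fit_gompertz(scaled)
        assert f1.params.lam == pytest.approx(f0.params.lam, rel=1e-6, abs=1e-12)
        assert f1.params.v0 == pytest.approx(f0.params.v0 * c, rel=1e-6)


class TestCompareModels:
    def test_identical_fits(self, make_gompertz_series):
        p = GrowthParameters(sgr0=0.002, lam=0.0, v0=1.0, t0=0.0)
        s = make_gompertz_series(p, [0, 300, 600, 900.0])
        cmp = compare_models(fit_exponential(s), fit_gompertz(s))
        assert cmp.delta_r2 == pytest.approx(0.0, abs=1e-12)
        assert cmp.sgr0_ratio == pytest.approx(1.0, rel=1e-8)
        assert cmp.verdict == "indeterminate"

    def test_strong_deceleration_favours_gompertz(self, make_gompertz_series):
        p = GrowthParameters(sgr0=0.01, lam=0.002, v0=1.0, t0=0.0)
        s = make_gompertz_series(p, np.arange(0.0, 2200.0, 300.0))
        e, g = fit_exponential(s), fit_gompertz(s)
        assert g.r2 > e.r2
        assert compare_models(e, g).verdict == "gompertz"

    def test_short_window_is_indeterminate_yet_formations_diverge(
        self, make_gompertz_series
    ):
        """The central clinical difficulty: on a short observation window
        both models fit essentially perfectly (delta r^2 below the margin)
        while their back-extrapolated formation times differ by years."""
        p = GrowthParameters(sgr0=0.008, lam=0.00025, v0=1e-9, t0=0.0)
        s = make_gompertz_series(p, [5000.0, 5180.0, 5360.0, 5540.0])
        e, g = fit_exponential(s, 1e-9), fit_gompertz(s, 1e-9)
        cmp = compare_models(e, g)
        assert cmp.verdict == "indeterminate"
        assert abs(cmp.formation_gap_days) > 2.0 * 365.0

    def test_lesion_mismatch_rejected(self, make_gompertz_series):
        p = GrowthParameters(sgr0=0.002, lam=0.0, v0=1.0, t0=0.0)
        a = make_gompertz_series(p, [0, 300, 600.0], lesion_id="a")
        b = make_gompertz_series(p, [0, 300, 600.0], lesion_id="b")
        with pytest.raises(DataError):
            compare_models(fit_exponential(a), fit_gompertz(b))
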