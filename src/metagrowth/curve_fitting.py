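"""Direct per-lesion curve fitting of the exponential and Gompertz models.

Both models are fitted by least squares in *log-volume* space: volume
measurement error is multiplicative, the exponential fit becomes an exact
linear regression, and the exponential model is exactly nested inside the
Gompertz one (lam = 0), so the Gompertz SSE can never exceed the
exponential SSE.

Each fit carries the back-extrapolated formation time — the time at which
the fitted curve passes the one-cell volume — and the growth rate the
curve had at that volume (``sgr_at_formation``).  For a decelerating
model these two quantities can differ drastically from their exponential
counterparts even when both curves fit the observed window equally well;
comparing them is the point of :func:`compare_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DataError, FitError, UnreachableVolumeError
from .growth_models import GrowthParameters, instantaneous_sgr, time_at_volume, volume_at
from .linearized_fit import ONE_CELL_VOLUME_CM3, fit_sgr_logv
from .sgr_estimation import LesionSeries, series_to_intervals

__all__ = ["DirectFit", "ModelComparison", "fit_exponential", "fit_gompertz", "compare_models"]

EXPONENTIAL = "exponential"
GOMPERTZ = "gompertz"

_SSE_TIE_TOL = 1e-10


@dataclass(frozen=True)
class DirectFit:
    """A per-lesion model fit.

    ``params`` is anchored at the first measurement time (t0) with v0 the
    fitted volume there.  ``formation_time`` is NaN when the fitted curve
    never reaches the one-cell volume (non-positive growth).
    """

    lesion_id: str
    model: str
    params: GrowthParameters
    r2: float
    sse: float
    formation_time: float
    sgr_at_formation: float
    n_points: int
    one_cell_volume: float
    converged: bool = True


def _r2_log_space(y: np.ndarray, resid: np.ndarray) -> tuple[float, float]:
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0.0:
        return 1.0 - sse / sst, sse
    return (1.0 if sse <= 1e-20 else 0.0), sse


def _formation(params: GrowthParameters, one_cell: float) -> tuple[float, float]:
    """(formation_time, sgr_at_formation); NaN time when unreachable."""
    sgr_cell = instantaneous_sgr(params, one_cell)
    try:
        t_form = time_at_volume(params, one_cell)
    except UnreachableVolumeError:
        t_form = math.nan
    if params.lam == 0.0 and params.sgr0 <= 0.0:
        t_form = math.nan
    return t_form, sgr_cell


def fit_exponential(
    series: LesionSeries, one_cell_volume: float = ONE_CELL_VOLUME_CM3
) -> DirectFit:
    """Exponential fit: exact linear least squares of ln(V) on t.

    The slope is the lesion's SGR; r^2 is computed in log-volume space.
    Two points give a saturated fit (r^2 = 1).
    """
    if len(series) < 2:
        raise FitError(
            f"lesion {series.lesion_id!r}: exponential fit needs >= 2 points, got {len(series)}"
        )
    t = series.times
    y = np.log(series.volumes)
    slope, intercept = np.polyfit(t, y, 1)
    t0 = float(t[0])
    params = GrowthParameters(sgr0=float(slope), lam=0.0, v0=float(np.exp(intercept + slope * t0)), t0=t0)
    resid = y - (intercept + slope * t)
    r2, sse = _r2_log_space(y, resid)
    t_form, sgr_cell = _formation(params, one_cell_volume)
    return DirectFit(
        lesion_id=series.lesion_id,
        model=EXPONENTIAL,
        params=params,
        r2=r2,
        sse=sse,
        formation_time=t_form,
        sgr_at_formation=sgr_cell,
        n_points=len(series),
        one_cell_volume=one_cell_volume,
    )


def _gompertz_log_volume(theta: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """ln V as a function of time-since-anchor; theta = (sgr_t0, lam, ln_v0)."""
    sgr_t0, lam, ln_v0 = theta
    x = lam * tau
    small = np.abs(x) < 1e-9
    with np.errstate(over="ignore", invalid="ignore"):
        gomp = np.where(small, sgr_t0 * tau, (sgr_t0 / max(lam, 1e-300)) * (-np.expm1(-x)))
    return ln_v0 + gomp


def _own_lambda_init(series: LesionSeries) -> float:
    """Initial lam from the lesion's own SGR-vs-lnV slope, if estimable."""
    intervals = series_to_intervals(series)
    if len(intervals) >= 3:
        try:
            fit = fit_sgr_logv(intervals, v0_assumed=1.0)
            if fit.slope < 0.0:
                return -fit.slope
        except DataError:
            pass
    return 1e-4


def fit_gompertz(
    series: LesionSeries, one_cell_volume: float = ONE_CELL_VOLUME_CM3
) -> DirectFit:
    """Gompertz fit: nonlinear least squares of ln(V) on t with lam >= 0.

    Free parameters are the growth rate at the first measurement, the
    deceleration constant (bounded below at 0 — accelerating growth is
    outside the model) and the log volume at the anchor.  Initialised from
    the exponential fit; the exact lam = 0 (exponential) solution is always
    evaluated as a candidate, so the Gompertz SSE never exceeds the
    exponential SSE.  Needs >= 3 points: with two, the deceleration is
    unidentifiable.

    ``sgr_at_formation`` reports the growth rate at the one-cell volume —
    the conventional SGR0 of a decelerating curve quoted at formation.
    """
    if len(series) < 3:
        raise FitError(
            f"lesion {series.lesion_id!r}: Gompertz fit needs >= 3 points, got {len(series)}"
        )
    t = series.times
    y = np.log(series.volumes)
    t0 = float(t[0])
    tau = t - t0

    exp_fit = fit_exponential(series, one_cell_volume)
    x0 = np.array([exp_fit.params.sgr0, _own_lambda_init(series), math.log(exp_fit.params.v0)])
    scale = np.array([max(abs(x0[0]), 1e-4), max(x0[1], 1e-5), max(abs(x0[2]), 1.0)])
    res = optimize.least_squares(
        lambda th: _gompertz_log_volume(th, tau) - y,
        x0,
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        x_scale=scale,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    sse_nl = float(np.sum(res.fun**2))
    theta_exp = np.array([exp_fit.params.sgr0, 0.0, math.log(exp_fit.params.v0)])
    # lam = 0 is in the feasible set: keep whichever of (optimizer, exact
    # exponential solution) has the smaller SSE, so nesting holds exactly.
    if sse_nl < exp_fit.sse - _SSE_TIE_TOL:
        theta, converged = res.x, bool(res.success)
    else:
        theta, converged = theta_exp, True
    sgr_t0, lam, ln_v0 = theta
    params = GrowthParameters(sgr0=float(sgr_t0), lam=float(lam), v0=float(np.exp(ln_v0)), t0=t0)
    resid = _gompertz_log_volume(theta, tau) - y
    r2, sse = _r2_log_space(y, resid)
    t_form, sgr_cell = _formation(params, one_cell_volume)
    return DirectFit(
        lesion_id=series.lesion_id,
        model=GOMPERTZ,
        params=params,
        r2=r2,
        sse=sse,
        formation_time=t_form,
        sgr_at_formation=sgr_cell,
        n_points=len(series),
        one_cell_volume=one_cell_volume,
        converged=converged,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side comparison of the two direct fits of one lesion.

    ``verdict`` is ``"indeterminate"`` when the r^2 difference is below the
    indifference margin — the typical clinical situation: both curves fit a
    short observation window equally well while implying formation times
    years apart.
    """

    lesion_id: str
    delta_r2: float
    formation_exponential: float
    formation_gompertz: float
    formation_gap_days: float
    sgr0_ratio: float
    verdict: str


def compare_models(
    exp_fit: DirectFit, gom_fit: DirectFit, indifference_margin: float = 0.02
) -> ModelComparison:
    """Compare the exponential and Gompertz fits of the same lesion.

    No winner is declared when |Delta r^2| is below ``indifference_margin``.
    """
    if exp_fit.lesion_id != gom_fit.lesion_id:
        raise DataError(
            f"lesion mismatch: {exp_fit.lesion_id!r} vs {gom_fit.lesion_id!r}"
        )
    if exp_fit.model != EXPONENTIAL or gom_fit.model != GOMPERTZ:
        raise DataError("compare_models expects (exponential fit, gompertz fit)")
    delta = gom_fit.r2 - exp_fit.r2
    if abs(delta) < indifference_margin:
        verdict = "indeterminate"
    else:
        verdict = GOMPERTZ if delta > 0 else EXPONENTIAL
    gap = gom_fit.formation_time - exp_fit.formation_time
    ratio = (
        gom_fit.sgr_at_formation / exp_fit.sgr_at_formation
        if exp_fit.sgr_at_formation != 0.0
        else math.inf
    )
    return ModelComparison(
        lesion_id=exp_fit.lesion_id,
        delta_r2=delta,
        formation_exponential=exp_fit.formation_time,
        formation_gompertz=gom_fit.formation_time,
        formation_gap_days=gap,
        sgr0_ratio=ratio,
        verdict=verdict,
    )
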