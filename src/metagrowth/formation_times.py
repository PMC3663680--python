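"""Per-lesion formation times by time-shifting the general growth curve.

Once the linearized regression has produced a general Gompertz curve —
anchored at the one-cell volume (1e-9 cm^3) — every metastasis of the
patient is assumed to follow that same curve, differing only in its time
origin.  Sliding the curve along the time axis to best fit a lesion's
measurements therefore dates the lesion: the optimal shift *is* the time
at which that lesion consisted of one cell.

The fit is 1-D least squares in log-volume space over the shift ``s``:

    minimise  sum_i [ ln v_i - ln V_general(t_i - s) ]^2 .

For noiseless data from the general curve the objective is exactly zero at
the true shift; a single measurement is solved in closed form by inverting
the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import DataError, UnreachableVolumeError
from .growth_models import GrowthParameters, time_at_volume, volume_at
from .sgr_estimation import LesionSeries

__all__ = ["FormationEstimate", "shift_fit", "estimate_all_formations"]


@dataclass(frozen=True)
class FormationEstimate:
    """Estimated time at which a lesion was one cell, with fit residual."""

    lesion_id: str
    formation_t: float
    sse: float
    n_points: int


def _pointwise_shifts(series: LesionSeries, general: GrowthParameters) -> np.ndarray:
    """Closed-form shift implied by each measurement alone.

    Raises :class:`UnreachableVolumeError` if any measured volume lies at
    or beyond the plateau of the general curve.
    """
    shifts = []
    for m in series.measurements:
        try:
            age = time_at_volume(general, m.v) - general.t0
        except UnreachableVolumeError as exc:
            raise UnreachableVolumeError(
                f"lesion {series.lesion_id!r}: measured volume {m.v:g} at t={m.t:g} "
                f"is unreachable under the general model ({exc})"
            ) from None
        shifts.append(m.t - age)
    return np.array(shifts)


def shift_fit(
    series: LesionSeries,
    general: GrowthParameters,
    initial_shift: float | None = None,
) -> FormationEstimate:
    """Slide the general curve in time to best fit one lesion.

    Parameters
    ----------
    series:
        The lesion's measurements (>= 1 point).
    general:
        The general growth curve; its ``v0`` should be the one-cell volume
        so that the returned shift is directly the formation time.
    initial_shift:
        Optional starting value for the 1-D optimiser; defaults to the
        median of the closed-form single-point shifts, which for monotone
        data lies next to the optimum.  The objective is unimodal for
        noiseless monotone series, so the result is start-independent.

    Returns the estimate with the shift ``s`` such that the shifted curve
    passes the one-cell volume at time ``s`` (when ``general.v0`` is one
    cell).
    """
    shifts = _pointwise_shifts(series, general)
    if len(series) == 1:
        return FormationEstimate(
            lesion_id=series.lesion_id,
            formation_t=float(shifts[0]),
            sse=0.0,
            n_points=1,
        )
    t = series.times
    y = np.log(series.volumes)

    def resid(s: np.ndarray) -> np.ndarray:
        return y - np.log(volume_at(general, general.t0 + (t - float(s[0]))))

    s0 = float(np.median(shifts)) if initial_shift is None else float(initial_shift)
    res = optimize.least_squares(resid, np.array([s0]), xtol=1e-14, ftol=1e-15, gtol=1e-15)
    # 1-D polish from the best closed-form candidate guards against a poor
    # user-supplied start on noisy data.
    best = res
    if initial_shift is not None:
        alt = optimize.least_squares(
            resid, np.array([float(np.median(shifts))]), xtol=1e-14, ftol=1e-15, gtol=1e-15
        )
        if float(np.sum(alt.fun**2)) < float(np.sum(best.fun**2)):
            best = alt
    s_hat = float(best.x[0])
    sse = float(np.sum(best.fun**2))
    return FormationEstimate(
        lesion_id=series.lesion_id, formation_t=s_hat, sse=sse, n_points=len(series)
    )


def estimate_all_formations(
    series_list: Sequence[LesionSeries], general: GrowthParameters
) -> list[FormationEstimate]:
    """Formation estimate for every lesion, sorted ascending by formation
    time (ties broken by lesion id)."""
    if not series_list:
        raise DataError("no lesion series supplied")
    out = []
    for s in series_list:
        try:
            out.append(shift_fit(s, general))
        except UnreachableVolumeError:
            raise
        except Exception as exc:  # re-raise with lesion context
            raise DataError(f"lesion {s.lesion_id!r}: shift fit failed ({exc})") from exc
    out.sort(key=lambda f: (f.formation_t, f.lesion_id))
    return out
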