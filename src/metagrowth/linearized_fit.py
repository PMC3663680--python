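"""The core estimator: OLS regression of interval SGR on log volume.

For Gompertzian growth the instantaneous SGR is linear in log volume,

    SGR = SGR0 - lam * ln(V / V0),

a relation that contains no time.  Regressing pooled (interval SGR,
log geometric-mean volume) records from *all* lesions of a patient
therefore estimates the parameters of a general Gompertz curve shared by
every metastasis, without knowing any lesion's age:

    lam  = -slope,
    SGR0 = intercept + slope * ln(V0_assumed),

where V0_assumed is the reference volume at which SGR0 is quoted —
by default the one-cell volume, 1e-9 cm^3.

Model selection: a significantly negative slope indicates that growth
deceleration dominates the observed rate variation (general Gompertz
model); otherwise the lesions are better described as growing
exponentially with heterogeneous rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError
from .sgr_estimation import IntervalEstimate

__all__ = [
    "GENERAL_GOMPERTZ",
    "HETEROGENEOUS_EXPONENTIAL",
    "ONE_CELL_VOLUME_CM3",
    "LinearizedFit",
    "LesionSGRSummary",
    "HeterogeneousSummary",
    "fit_sgr_logv",
    "describe_heterogeneous",
]

GENERAL_GOMPERTZ = "general_gompertz"
HETEROGENEOUS_EXPONENTIAL = "heterogeneous_exponential"

#: Volume of a single cell in cm^3 — the default reference volume for SGR0
#: and the back-extrapolation target for formation times.
ONE_CELL_VOLUME_CM3 = 1e-9


@dataclass(frozen=True)
class LinearizedFit:
    """Result of the SGR-vs-ln(volume) regression.

    ``lam = -slope`` (clipped at 0 when the slope is non-negative, with
    ``slope_nonnegative`` flagged) and ``sgr0`` is the growth rate the
    fitted line predicts at ``v0_assumed``.
    """

    intercept: float
    slope: float
    lam: float
    sgr0: float
    v0_assumed: float
    r2: float
    p_slope: float
    n_points: int
    selected_model: str
    alpha: float
    slope_nonnegative: bool = False


def fit_sgr_logv(
    intervals: Sequence[IntervalEstimate],
    v0_assumed: float = ONE_CELL_VOLUME_CM3,
    alpha: float = 0.05,
) -> LinearizedFit:
    """Unweighted OLS of interval SGR on log geometric-mean volume.

    All records from all lesions are pooled; negative and zero SGR values
    are always included.  ``p_slope`` is the two-sided t-test of zero
    slope on n-2 degrees of freedom.  The general Gompertz model is
    selected iff the slope is negative and significant at ``alpha``.

    Raises
    ------
    DataError
        Fewer than 3 records, or all log volumes identical (degenerate
        design — the slope is unidentifiable).
    """
    if v0_assumed <= 0.0:
        raise ValueError(f"v0_assumed must be positive, got {v0_assumed!r}")
    if len(intervals) < 3:
        raise DataError(
            f"linearized fit needs >= 3 interval records, got {len(intervals)}"
        )
    x = np.array([iv.log_gm_volume for iv in intervals])
    y = np.array([iv.sgr for iv in intervals])
    if np.ptp(x) == 0.0:
        raise DataError("degenerate design: all log geometric-mean volumes identical")

    res = stats.linregress(x, y)
    slope = float(res.slope)
    intercept = float(res.intercept)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)

    nonneg = slope >= 0.0
    lam = 0.0 if nonneg else -slope
    sgr0 = intercept + slope * math.log(v0_assumed)
    selected = (
        GENERAL_GOMPERTZ if (slope < 0.0 and p < alpha) else HETEROGENEOUS_EXPONENTIAL
    )
    return LinearizedFit(
        intercept=intercept,
        slope=slope,
        lam=lam,
        sgr0=sgr0,
        v0_assumed=v0_assumed,
        r2=r2,
        p_slope=p,
        n_points=len(intervals),
        selected_model=selected,
        alpha=alpha,
        slope_nonnegative=nonneg,
    )


@dataclass(frozen=True)
class LesionSGRSummary:
    """Time-weighted mean exponential growth rate of one lesion.

    The time-weighted mean of interval SGRs equals the total log growth
    divided by the total observed time, i.e. the slope of the two-point
    exponential fit through the endpoints of the observation window.
    """

    lesion_id: str
    mean_sgr: float
    total_days: float
    n_intervals: int


@dataclass(frozen=True)
class HeterogeneousSummary:
    """Per-lesion exponential rates under the heterogeneous model."""

    lesions: tuple[LesionSGRSummary, ...]
    sgr_min: float
    sgr_max: float


def describe_heterogeneous(intervals: Sequence[IntervalEstimate]) -> HeterogeneousSummary:
    """Per-lesion mean SGR (weighted by interval length) and the
    across-lesion range, for reporting when the heterogeneous-exponential
    model is selected."""
    if not intervals:
        raise DataError("no interval records to summarise")
    by_lesion: dict[str, list[IntervalEstimate]] = {}
    for iv in intervals:
        by_lesion.setdefault(iv.lesion_id, []).append(iv)
    summaries = []
    for lesion_id in sorted(by_lesion):
        ivs = by_lesion[lesion_id]
        total_t = sum(iv.t2 - iv.t1 for iv in ivs)
        total_ln = sum(iv.sgr * (iv.t2 - iv.t1) for iv in ivs)
        summaries.append(
            LesionSGRSummary(
                lesion_id=lesion_id,
                mean_sgr=total_ln / total_t,
                total_days=total_t,
                n_intervals=len(ivs),
            )
        )
    rates = [s.mean_sgr for s in summaries]
    return HeterogeneousSummary(
        lesions=tuple(summaries), sgr_min=min(rates), sgr_max=max(rates)
    )
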