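"""Metastasis formation rate: exponential increase of lesion count.

Sorting the per-lesion formation times and ranking them 1..n gives the
cumulative number of metastases as a function of time.  The count is
modelled as increasing exponentially from 1 at the formation of the first
metastasis:

    N(t) = exp[ k * (t - t_first) ],

fitted by through-origin least squares of ln(rank) on time since the first
formation (an intercept would break N = 1 at t_first).  The rate constant
k is reported per year (1 year = 365 days); internally time stays in days.

Because only differences of formation times enter, the fit is independent
of the patient epoch — and of whether each metastasis seeded from the
primary tumour or from another metastasis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError
from .formation_times import FormationEstimate

__all__ = ["RateFit", "fit_formation_rate", "predict_count"]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class RateFit:
    """Exponential formation-rate fit.

    ``k`` is per year; ``t_first`` (days) is the formation time of the
    first metastasis, the time origin of the count model.
    """

    k: float
    t_first: float
    r2: float
    n_lesions: int


def fit_formation_rate(formations: Sequence[FormationEstimate]) -> RateFit:
    """Fit ln(cumulative count) = k * (t - t_first) through the origin.

    r^2 is computed in ln-count space about the origin-constrained model
    (uncentred, consistent with the absence of an intercept).

    Raises
    ------
    DataError
        Fewer than 2 finite formation times, or all formation times
        coincident (the rate is unidentifiable).
    """
    times = sorted(f.formation_t for f in formations if math.isfinite(f.formation_t))
    if len(times) < 2:
        raise DataError(
            f"formation-rate fit needs >= 2 finite formation times, got {len(times)}"
        )
    t_first = times[0]
    x = np.array(times) - t_first  # days since first formation
    y = np.log(np.arange(1, len(times) + 1, dtype=float))
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise DataError("all formation times coincide: formation rate unidentifiable")
    slope = float(np.sum(x * y)) / sxx  # per day
    resid = y - slope * x
    syy = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid**2)) / syy
    return RateFit(
        k=slope * DAYS_PER_YEAR, t_first=t_first, r2=r2, n_lesions=len(times)
    )


def predict_count(fit: RateFit, t: float) -> float:
    """Expected number of metastases present at time ``t`` (days).

    Returns the continuous expectation ``exp(k*(t - t_first))`` — exactly 1
    at the first formation.  Values for ``t < t_first`` are below 1 and
    flagged with a warning: they extrapolate before the first metastasis
    existed.
    """
    if t < fit.t_first:
        warnings.warn(
            f"predicting count at t={t:g} d, before the first formation "
            f"(t_first={fit.t_first:g} d): extrapolation below one metastasis",
            stacklevel=2,
        )
    return math.exp(fit.k / DAYS_PER_YEAR * (t - fit.t_first))
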