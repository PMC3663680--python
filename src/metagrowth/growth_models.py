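"""Closed-form growth-curve mathematics shared by every estimator.

Two models of tumour volume as a function of time are supported through a
single parameter container:

* exponential growth, ``V(t) = V0 * exp(SGR * (t - t0))``, in which the
  specific growth rate SGR — the relative volume increase per unit time,
  ``(1/V) dV/dt`` — is constant; and
* Gompertzian growth,
  ``V(t) = V0 * exp[(SGR0/lam) * (1 - exp(-lam*(t - t0)))]``,
  in which growth decelerates: the instantaneous SGR decays exponentially
  with time at rate ``lam`` (the growth deceleration constant) and the
  volume saturates at the plateau ``V0 * exp(SGR0/lam)``.

The exponential model is the ``lam = 0`` member of the same family, not a
separate type; every routine in this module handles both branches and is
continuous in ``lam`` at zero.

Units: time in days, volumes in cm^3 (or any consistent arbitrary unit),
SGR in fraction/day.  Months and %/day appear only in formatting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NoDoublingTimeError, UnreachableVolumeError

__all__ = [
    "GrowthParameters",
    "volume_at",
    "instantaneous_sgr",
    "time_at_volume",
    "sgr_to_dt",
    "dt_to_sgr",
    "days_to_months",
    "format_months",
]

#: Below this value of ``lam * |t - t0|`` the Gompertz exponent is evaluated
#: on its exponential (lam -> 0) branch to avoid 0/0 loss of precision.
LAMBDA_SWITCH_TOL = 1e-9


@dataclass(frozen=True)
class GrowthParameters:
    """Parameters (SGR0, lam, V0, t0) of an exponential or Gompertz curve.

    Attributes
    ----------
    sgr0:
        Specific growth rate at the reference time ``t0`` (fraction/day).
        Negative values are legal — non-growing lesions are never excluded.
    lam:
        Growth deceleration constant (1/day); ``lam == 0`` selects the
        exponential model.
    v0:
        Volume at the reference time (must be positive).
    t0:
        Reference time (days).
    """

    sgr0: float
    lam: float = 0.0
    v0: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.sgr0):
            raise ValueError(f"sgr0 must be finite, got {self.sgr0!r}")
        if not (self.lam >= 0.0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be finite and >= 0, got {self.lam!r}")
        if not (self.v0 > 0.0 and math.isfinite(self.v0)):
            raise ValueError(f"v0 must be finite and > 0, got {self.v0!r}")
        if not math.isfinite(self.t0):
            raise ValueError(f"t0 must be finite, got {self.t0!r}")

    @property
    def is_exponential(self) -> bool:
        return self.lam == 0.0

    @property
    def plateau_volume(self) -> float:
        """Asymptotic volume as t -> +inf; ``inf`` for exponential growth
        with sgr0 > 0. For lam > 0 this is ``v0 * exp(sgr0/lam)`` (a floor
        rather than a ceiling when sgr0 < 0)."""
        if self.lam > 0.0:
            return self.v0 * math.exp(self.sgr0 / self.lam)
        if self.sgr0 > 0.0:
            return math.inf
        if self.sgr0 < 0.0:
            return 0.0
        return self.v0


def _log_relative_volume(params: GrowthParameters, t):
    """ln(V(t)/V0) for scalar or array t, continuous across lam -> 0."""
    tau = np.asarray(t, dtype=float) - params.t0
    if not np.all(np.isfinite(tau)):
        raise ValueError("time must be finite")
    x = params.lam * tau
    small = np.abs(x) < LAMBDA_SWITCH_TOL
    if params.lam == 0.0:
        return params.sgr0 * tau
    # -expm1(-x)/x -> 1 as x -> 0; use the linear branch only below the
    # switch tolerance where the ratio is 1 to machine precision.
    with np.errstate(over="ignore"):
        gomp = (params.sgr0 / params.lam) * (-np.expm1(-x))
    return np.where(small, params.sgr0 * tau, gomp)


def volume_at(params: GrowthParameters, t):
    """Volume of the growth curve at time ``t`` (days).

    Accepts a scalar or array of times; returns the matching shape.
    """
    out = params.v0 * np.exp(_log_relative_volume(params, t))
    return float(out) if np.ndim(t) == 0 else out


def instantaneous_sgr(params: GrowthParameters, v) -> float:
    """Instantaneous specific growth rate at volume ``v``.

    For the Gompertz model the SGR is a linear function of log volume,
    ``SGR(V) = sgr0 - lam * ln(V/V0)`` — the time-eliminated form on which
    the linearized estimator is built.  For ``lam == 0`` it is constant.
    """
    varr = np.asarray(v, dtype=float)
    if np.any(varr <= 0.0) or not np.all(np.isfinite(varr)):
        raise ValueError("volume must be positive and finite")
    out = params.sgr0 - params.lam * np.log(varr / params.v0)
    return float(out) if np.ndim(v) == 0 else out


def time_at_volume(params: GrowthParameters, v_target: float) -> float:
    """Invert the growth curve: the unique time at which it passes
    ``v_target``.

    Used to back-extrapolate a fitted curve to the one-cell volume
    (1e-9 cm^3) when estimating a lesion's formation time.

    Raises
    ------
    UnreachableVolumeError
        If ``v_target`` lies outside the curve's range, e.g. at or above
        the Gompertz plateau ``v0 * exp(sgr0/lam)``.
    """
    if not (v_target > 0.0 and math.isfinite(v_target)):
        raise ValueError(f"v_target must be positive and finite, got {v_target!r}")
    log_ratio = math.log(v_target / params.v0)
    if params.lam == 0.0:
        if params.sgr0 == 0.0:
            if log_ratio == 0.0:
                return params.t0
            raise UnreachableVolumeError(
                "constant curve (sgr0=0, lam=0) never reaches a different volume"
            )
        return params.t0 + log_ratio / params.sgr0
    if params.sgr0 == 0.0:
        if log_ratio == 0.0:
            return params.t0
        raise UnreachableVolumeError("flat curve (sgr0=0) never leaves v0")
    x = (params.lam / params.sgr0) * log_ratio
    if x >= 1.0:
        raise UnreachableVolumeError(
            f"volume {v_target:g} is unreachable: at or beyond the plateau "
            f"{params.plateau_volume:g} of the Gompertz curve"
        )
    # log1p keeps precision as lam -> 0, where t -> t0 + log_ratio/sgr0.
    return params.t0 - math.log1p(-x) / params.lam


def sgr_to_dt(sgr: float) -> float:
    """Volume doubling time (days) of a growth rate: ``DT = ln2 / SGR``.

    Raises :class:`NoDoublingTimeError` for ``sgr <= 0`` (a shrinking or
    static tumour never doubles) and ``ValueError`` for non-finite input.
    """
    if not math.isfinite(sgr):
        raise ValueError(f"sgr must be finite, got {sgr!r}")
    if sgr <= 0.0:
        raise NoDoublingTimeError(f"SGR {sgr:g}/day has no finite doubling time")
    return math.log(2.0) / sgr


def dt_to_sgr(dt: float) -> float:
    """Specific growth rate (fraction/day) from a doubling time in days."""
    if not math.isfinite(dt):
        raise ValueError(f"dt must be finite, got {dt!r}")
    if dt <= 0.0:
        raise ValueError(f"doubling time must be positive, got {dt!r}")
    return math.log(2.0) / dt


def days_to_months(days: float) -> int:
    """Convert days to whole months for reporting.

    Convention: 1 month = 30 days, rounded half away from zero.  Days are
    the canonical internal unit; months appear only in formatted output.
    """
    months = days / 30.0
    return int(math.floor(abs(months) + 0.5)) * (1 if months >= 0 else -1)


def format_months(days: float) -> str:
    """Human-readable month string for a duration in days, e.g. ``"2 months"``."""
    m = days_to_months(days)
    return f"{m} month" if abs(m) == 1 else f"{m} months"
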