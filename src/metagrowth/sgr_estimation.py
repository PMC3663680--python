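"""Interval growth-rate records from longitudinal volume series.

The first two stages of the patient-level pipeline: for each pair of
consecutive volume measurements of a lesion, compute

* the interval specific growth rate ``SGR = ln(V2/V1) / (t2 - t1)``, and
* the logarithm of the geometric mean of the two volumes,
  ``(ln V1 + ln V2) / 2``.

The (SGR, ln V) pairs from all lesions of a patient feed the linearized
Gompertz regression; time is deliberately eliminated so lesions of unknown
age can be pooled.  Zero and negative growth rates are kept — excluding
them would bias the regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError

__all__ = [
    "VolumeMeasurement",
    "LesionSeries",
    "IntervalEstimate",
    "interval_sgr",
    "paired_log_volume",
    "series_to_intervals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeMeasurement:
    """One lesion's volume at one time point.

    ``t`` is in days relative to a patient-level epoch, ``v`` in cm^3
    (strictly positive — a lesion below visibility yields no record).
    """

    lesion_id: str
    t: float
    v: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise DataError(f"lesion {self.lesion_id!r}: time must be finite, got {self.t!r}")
        if not (self.v > 0.0 and math.isfinite(self.v)):
            raise DataError(
                f"lesion {self.lesion_id!r}: volume must be positive and finite, got {self.v!r}"
            )


@dataclass(frozen=True)
class LesionSeries:
    """Ordered volume measurements of a single lesion.

    Measurements are sorted by time on construction; duplicate time points
    are rejected (an interval growth rate over a zero-length interval is
    undefined).
    """

    lesion_id: str
    measurements: tuple[VolumeMeasurement, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ms = tuple(sorted(self.measurements, key=lambda m: m.t))
        if not ms:
            raise DataError(f"lesion {self.lesion_id!r}: series has no measurements")
        for m in ms:
            if m.lesion_id != self.lesion_id:
                raise DataError(
                    f"series {self.lesion_id!r} contains a measurement for {m.lesion_id!r}"
                )
        for a, b in zip(ms, ms[1:]):
            if b.t == a.t:
                raise DataError(
                    f"lesion {self.lesion_id!r}: duplicate measurement time t={a.t:g}"
                )
        object.__setattr__(self, "measurements", ms)

    @classmethod
    def from_arrays(
        cls, lesion_id: str, times: Iterable[float], volumes: Iterable[float]
    ) -> "LesionSeries":
        ms = tuple(
            VolumeMeasurement(lesion_id, float(t), float(v)) for t, v in zip(times, volumes)
        )
        return cls(lesion_id, ms)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def times(self) -> np.ndarray:
        return np.array([m.t for m in self.measurements])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([m.v for m in self.measurements])

    @property
    def span(self) -> float:
        """Duration covered by the series, in days."""
        return self.measurements[-1].t - self.measurements[0].t


@dataclass(frozen=True)
class IntervalEstimate:
    """One consecutive-pair record: interval SGR paired with the log
    geometric-mean volume.

    ``t_mid`` is carried for diagnostics only; the linearized regression
    uses ``log_gm_volume`` — time is eliminated by construction.
    """

    lesion_id: str
    sgr: float
    log_gm_volume: float
    t_mid: float
    t1: float
    t2: float


def interval_sgr(v1: float, v2: float, t1: float, t2: float) -> float:
    """Interval specific growth rate ``ln(V2/V1) / (t2 - t1)`` (per day).

    Zero and negative values are returned unchanged.
    """
    if not (v1 > 0.0 and v2 > 0.0):
        raise DataError(f"volumes must be positive, got v1={v1!r}, v2={v2!r}")
    if not t2 > t1:
        raise DataError(f"need t2 > t1, got t1={t1!r}, t2={t2!r}")
    return math.log(v2 / v1) / (t2 - t1)


def paired_log_volume(v1: float, v2: float) -> float:
    """Log of the geometric mean of two volumes: ``(ln v1 + ln v2) / 2``."""
    if not (v1 > 0.0 and v2 > 0.0):
        raise DataError(f"volumes must be positive, got v1={v1!r}, v2={v2!r}")
    return 0.5 * (math.log(v1) + math.log(v2))


def series_to_intervals(series: LesionSeries) -> list[IntervalEstimate]:
    """Interval records for every pair of *consecutive* measurements.

    Returns exactly ``n - 1`` records for ``n`` measurements, in time
    order.  A single-measurement series yields an empty list (logged, not
    an error): such a lesion contributes nothing to the regression but may
    still be shift-fitted against the general curve.
    """
    ms = series.measurements
    if len(ms) < 2:
        logger.info(
            "lesion %r: only %d measurement(s), no interval records", series.lesion_id, len(ms)
        )
        return []
    out = []
    for a, b in zip(ms, ms[1:]):
        out.append(
            IntervalEstimate(
                lesion_id=series.lesion_id,
                sgr=interval_sgr(a.v, b.v, a.t, b.t),
                log_gm_volume=paired_log_volume(a.v, b.v),
                t_mid=0.5 * (a.t + b.t),
                t1=a.t,
                t2=b.t,
            )
        )
    return out


def all_intervals(series_list: Sequence[LesionSeries]) -> list[IntervalEstimate]:
    """Pool interval records across every lesion of a patient."""
    out: list[IntervalEstimate] = []
    for s in series_list:
        out.extend(series_to_intervals(s))
    return out
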