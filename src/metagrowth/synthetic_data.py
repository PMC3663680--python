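"""Synthetic data: the worked Gompertz example and a metastatic-cohort simulator.

Two generators live here.

``make_appendix_table`` reproduces, at full precision, the deterministic
worked example of a single Gompertz tumour (SGR0 = 0.001/day and V0 = 1 at
t = 0, lam = 0.0003/day) measured every 180 days for ten years, together
with the interval SGR and log geometric-mean volume of each consecutive
pair — the reference table against which the interval and regression
machinery is validated cell-for-cell.

``simulate_patient`` emulates the structure of real patient data: a cohort
of metastases appearing over time, each growing from the one-cell volume
(1e-9 cm^3) either along a shared general Gompertz curve or exponentially
with lesion-specific rates, observed on a sparse visit schedule with
multiplicative lognormal measurement noise and a visibility threshold.
Ground-truth formation times and growth rates are returned alongside the
observed series, so parameter-recovery tests can compare pipeline output
to the generating truth.

Default scenario values mirror a clinically realistic hepatic cohort: a
shared Gompertz curve with SGR0 = 0.79 %/day at one cell and
lam = 0.00023/day, lesions appearing at k = 0.5/year, eight semiannual
visits beginning ~12 years after the first lesion forms, a 0.1 cm^3
detection threshold, and 10 % volume measurement error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DataError
from .growth_models import GrowthParameters, volume_at
from .linearized_fit import GENERAL_GOMPERTZ, HETEROGENEOUS_EXPONENTIAL, ONE_CELL_VOLUME_CM3
from .sgr_estimation import LesionSeries, VolumeMeasurement, interval_sgr, paired_log_volume

__all__ = [
    "APPENDIX_PARAMS",
    "APPENDIX_REFERENCE_ROWS",
    "diff_appendix_table",
    "make_appendix_table",
    "format_appendix_table",
    "appendix_series",
    "CohortScenario",
    "SimulatedPatient",
    "simulate_patient",
    "write_measurements_csv",
    "write_truth_json",
    "round_half_away",
]

#: Parameters of the worked single-tumour example: SGR0 = 0.1 %/day and
#: V0 = 1 (arbitrary unit) at t = 0, deceleration lam = 0.0003/day.
APPENDIX_PARAMS = GrowthParameters(sgr0=0.001, lam=0.0003, v0=1.0, t0=0.0)

_APPENDIX_TIMES = np.arange(0, 3601, 180)


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of the reference tables,
    as opposed to Python's default round-half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def make_appendix_table() -> pd.DataFrame:
    """The worked-example table at full precision.

    Columns: ``t_days``, ``t_months``, ``v`` (Gompertz volume),
    ``v_geomean`` (geometric mean of the pair ending at this row),
    ``ln_v`` (its log) and ``sgr`` (interval SGR of the pair).  The first
    row is the initial condition: volume 1, ln 0, and the *instantaneous*
    SGR0 rather than an interval value.
    """
    ts = _APPENDIX_TIMES
    vs = volume_at(APPENDIX_PARAMS, ts)
    rows = []
    for i, t in enumerate(ts):
        if i == 0:
            gm, lnv, sgr = vs[0], math.log(vs[0]), APPENDIX_PARAMS.sgr0
        else:
            gm = math.exp(paired_log_volume(vs[i - 1], vs[i]))
            lnv = paired_log_volume(vs[i - 1], vs[i])
            sgr = interval_sgr(vs[i - 1], vs[i], float(ts[i - 1]), float(ts[i]))
        rows.append(
            {
                "t_days": int(t),
                "t_months": int(t) // 30,
                "v": float(vs[i]),
                "v_geomean": float(gm),
                "ln_v": float(lnv),
                "sgr": float(sgr),
            }
        )
    return pd.DataFrame(rows)


def format_appendix_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Round the worked-example table to its printed precision:
    volumes and log volumes to 2 decimals, SGR to 5 decimals."""
    if table is None:
        table = make_appendix_table()
    out = table.copy()
    for col, nd in (("v", 2), ("v_geomean", 2), ("ln_v", 2), ("sgr", 5)):
        out[col] = [round_half_away(x, nd) for x in out[col]]
    return out


#: Reference rounding of the worked-example table (t days, t months,
#: volume, geometric-mean volume, ln gm volume, interval SGR).  Frozen so
#: regenerated tables can be diffed against it.
APPENDIX_REFERENCE_ROWS: tuple[tuple[int, int, float, float, float, float], ...] = (
    (0, 0, 1.00, 1.00, 0.00, 0.00100),
    (180, 6, 1.19, 1.09, 0.09, 0.00097),
    (360, 12, 1.41, 1.29, 0.26, 0.00092),
    (540, 18, 1.65, 1.52, 0.42, 0.00087),
    (720, 24, 1.91, 1.77, 0.57, 0.00083),
    (900, 30, 2.20, 2.05, 0.72, 0.00078),
    (1080, 36, 2.52, 2.35, 0.86, 0.00074),
    (1260, 42, 2.86, 2.68, 0.99, 0.00070),
    (1440, 48, 3.22, 3.03, 1.11, 0.00067),
    (1620, 54, 3.61, 3.41, 1.23, 0.00063),
    (1800, 60, 4.02, 3.81, 1.34, 0.00060),
    (1980, 66, 4.45, 4.23, 1.44, 0.00057),
    (2160, 72, 4.90, 4.67, 1.54, 0.00054),
    (2340, 78, 5.37, 5.13, 1.64, 0.00051),
    (2520, 84, 5.86, 5.61, 1.72, 0.00048),
    (2700, 90, 6.36, 6.11, 1.81, 0.00046),
    (2880, 96, 6.88, 6.62, 1.89, 0.00043),
    (3060, 102, 7.41, 7.14, 1.97, 0.00041),
    (3240, 108, 7.94, 7.67, 2.04, 0.00039),
    (3420, 114, 8.49, 8.21, 2.11, 0.00037),
    (3600, 120, 9.04, 8.76, 2.17, 0.00035),
)


def diff_appendix_table() -> list[str]:
    """Regenerate the worked-example table, round it, and diff it against
    the frozen reference.  Returns a list of human-readable mismatch
    descriptions (empty when the regeneration is exact)."""
    got = format_appendix_table()
    mismatches = []
    for row, ref in zip(got.itertuples(index=False), APPENDIX_REFERENCE_ROWS):
        computed = (row.t_days, row.t_months, row.v, row.v_geomean, row.ln_v, row.sgr)
        for name, c, r in zip(got.columns, computed, ref):
            if c != r:
                mismatches.append(f"t={ref[0]} {name}: computed {c!r} != reference {r!r}")
    return mismatches


def appendix_series(lesion_id: str = "appendix") -> LesionSeries:
    """The worked example's 21 exact volumes as a single-lesion series."""
    vs = volume_at(APPENDIX_PARAMS, _APPENDIX_TIMES)
    return LesionSeries.from_arrays(lesion_id, _APPENDIX_TIMES.astype(float), vs)


@dataclass(frozen=True)
class CohortScenario:
    """Ground-truth description of a simulated metastatic cohort.

    Attributes
    ----------
    truth_model:
        ``"general_gompertz"`` — every lesion follows one shared Gompertz
        curve from the one-cell volume; or ``"heterogeneous_exponential"``
        — each lesion grows exponentially at its own rate.
    sgr0:
        Growth rate (fraction/day) at the one-cell volume: the shared SGR0
        of the Gompertz truth, or the median per-lesion rate of the
        heterogeneous truth.
    lam:
        Growth deceleration constant (1/day); must be 0 for the
        heterogeneous-exponential truth.
    sgr_dispersion:
        Lognormal sigma of per-lesion rates about ``sgr0`` (heterogeneous
        truth only).
    formation_rate_k:
        Exponential increase constant of the cumulative lesion count, per
        year.  Lesion i+1 forms after a gap with mean
        ``(ln(i+1) - ln i)/k`` so the count grows exponentially at rate k
        in expectation; ``formation_jitter`` (lognormal sigma) randomises
        the gaps around those means.
    visit_times:
        Absolute measurement times (days); the first lesion forms at day 0.
    noise_cv:
        Coefficient of variation of the multiplicative volume measurement
        error.  Noise multipliers are exp(N(-sigma^2/2, sigma)) with
        sigma = ln(1 + CV): mean-unbiased in volume, hence a -sigma^2/2
        mean in log space.
    detection_volume:
        True volume below which a lesion yields no record at a visit.
    """

    truth_model: str = GENERAL_GOMPERTZ
    sgr0: float = 0.0079
    lam: float = 0.00023
    sgr_dispersion: float = 0.35
    formation_rate_k: float = 0.5
    n_lesions: int = 6
    visit_times: tuple[float, ...] = tuple(4500.0 + 180.0 * i for i in range(8))
    noise_cv: float = 0.1
    detection_volume: float = 0.1
    one_cell_volume: float = ONE_CELL_VOLUME_CM3
    formation_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_model not in (GENERAL_GOMPERTZ, HETEROGENEOUS_EXPONENTIAL):
            raise ValueError(f"unknown truth_model {self.truth_model!r}")
        if self.truth_model == HETEROGENEOUS_EXPONENTIAL and self.lam != 0.0:
            raise ValueError("heterogeneous_exponential truth requires lam = 0")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.noise_cv < 0.0:
            raise ValueError("noise_cv must be >= 0")
        if not (self.detection_volume > self.one_cell_volume > 0.0):
            raise ValueError("need detection_volume > one_cell_volume > 0")
        if len(self.visit_times) < 1:
            raise ValueError("need at least one visit time")
        if self.formation_rate_k <= 0.0:
            raise ValueError("formation_rate_k must be positive")


@dataclass(frozen=True)
class SimulatedPatient:
    """Observed series plus generating truth for one simulated patient.

    ``series`` contains only lesions with at least one detected
    measurement; ``truth_formations`` and ``truth_sgr0`` cover every
    lesion, detected or not.
    """

    scenario: CohortScenario
    series: tuple[LesionSeries, ...]
    truth_formations: dict[str, float]
    truth_sgr0: dict[str, float]
    truth_params: dict[str, GrowthParameters] = field(default_factory=dict)


def _lesion_id(i: int) -> str:
    return f"L{i + 1:02d}"


def simulate_patient(scenario: CohortScenario) -> SimulatedPatient:
    """Simulate one patient's metastatic cohort under ``scenario``.

    Deterministic for a fixed scenario (including its ``seed``): noise is
    drawn for every lesion x visit in a fixed order regardless of
    detection, so changing the detection threshold does not reshuffle the
    random stream.

    Raises
    ------
    DataError
        If no lesion is ever detectable, with diagnostics of the largest
        volume reached.
    """
    rng = np.random.default_rng(scenario.seed)
    k_per_day = scenario.formation_rate_k / 365.0

    # Formation times: exponential accumulation in expectation.
    formations = [0.0]
    for i in range(1, scenario.n_lesions):
        mean_gap = (math.log(i + 1) - math.log(i)) / k_per_day
        if scenario.formation_jitter > 0.0:
            sig = scenario.formation_jitter
            gap = mean_gap * rng.lognormal(mean=-0.5 * sig**2, sigma=sig)
        else:
            gap = mean_gap
        formations.append(formations[-1] + gap)

    # Per-lesion growth curves from one cell at formation.
    params: dict[str, GrowthParameters] = {}
    sgr0s: dict[str, float] = {}
    for i, f in enumerate(formations):
        lid = _lesion_id(i)
        if scenario.truth_model == GENERAL_GOMPERTZ:
            sgr = scenario.sgr0
        else:
            sgr = scenario.sgr0 * rng.lognormal(mean=0.0, sigma=scenario.sgr_dispersion)
        sgr0s[lid] = sgr
        params[lid] = GrowthParameters(
            sgr0=sgr, lam=scenario.lam, v0=scenario.one_cell_volume, t0=f
        )

    sigma = math.log(1.0 + scenario.noise_cv)
    series: list[LesionSeries] = []
    max_true = 0.0
    for i in range(scenario.n_lesions):
        lid = _lesion_id(i)
        p = params[lid]
        kept: list[VolumeMeasurement] = []
        for t in scenario.visit_times:
            if t < p.t0:
                continue  # lesion not yet formed
            true_v = volume_at(p, t)
            max_true = max(max_true, true_v)
            mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) if sigma > 0 else 1.0
            if true_v >= scenario.detection_volume:
                kept.append(VolumeMeasurement(lid, float(t), true_v * mult))
        if kept:
            series.append(LesionSeries(lid, tuple(kept)))
    if not series:
        raise DataError(
            f"scenario produced no detectable lesion: largest true volume "
            f"{max_true:.3g} cm^3 never reached the detection threshold "
            f"{scenario.detection_volume:g} cm^3 at any visit "
            f"(visits {scenario.visit_times[0]:g}..{scenario.visit_times[-1]:g} d)"
        )
    return SimulatedPatient(
        scenario=scenario,
        series=tuple(series),
        truth_formations={_lesion_id(i): formations[i] for i in range(scenario.n_lesions)},
        truth_sgr0=sgr0s,
        truth_params=params,
    )


def write_measurements_csv(patient: SimulatedPatient, path) -> None:
    """Write the observed series in the measurement-CSV dialect the I/O
    layer reads (columns lesion_id, time, volume_cm3)."""
    rows = [
        {"lesion_id": m.lesion_id, "time": m.t, "volume_cm3": m.v}
        for s in patient.series
        for m in s.measurements
    ]
    pd.DataFrame(rows, columns=["lesion_id", "time", "volume_cm3"]).to_csv(path, index=False)


def write_truth_json(patient: SimulatedPatient, path) -> None:
    """Truth sidecar for test harnesses: scenario, formation times, rates."""
    sc = patient.scenario
    payload = {
        "scenario": {
            "truth_model": sc.truth_model,
            "sgr0": sc.sgr0,
            "lam": sc.lam,
            "sgr_dispersion": sc.sgr_dispersion,
            "formation_rate_k": sc.formation_rate_k,
            "n_lesions": sc.n_lesions,
            "visit_times": list(sc.visit_times),
            "noise_cv": sc.noise_cv,
            "detection_volume": sc.detection_volume,
            "one_cell_volume": sc.one_cell_volume,
            "formation_jitter": sc.formation_jitter,
            "seed": sc.seed,
        },
        "truth_formations": patient.truth_formations,
        "truth_sgr0": patient.truth_sgr0,
        "detected_lesions": [s.lesion_id for s in patient.series],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
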