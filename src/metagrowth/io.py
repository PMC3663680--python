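"""File I/O and patient-level pipeline orchestration.

``read_measurements`` parses the longitudinal measurement table (CSV/TSV,
columns ``lesion_id``, ``time``, ``volume_cm3``; times as float days or
ISO dates) into a validated :class:`PatientDataset`.

``analyze_patient`` runs the five-stage pipeline end to end:

1. interval SGRs for each pair of consecutive measurements per lesion;
2. log geometric-mean volumes per pair;
3. pooled OLS of SGR on ln V, mapped to the general Gompertz parameters
   (SGR0, lam) with V0 at one cell, plus model selection;
4. construction of the general growth curve from those parameters;
5. per-lesion formation times — by sliding the general curve in time
   (Gompertz branch) or by back-extrapolating each lesion's own
   exponential fit (heterogeneous branch) — and the exponential
   metastasis-formation-rate fit.

Direct exponential and Gompertz fits per lesion are always attempted as
well, for the model-comparison table.  All internal times are days and
volumes cm^3; %/day, months and calendar years appear only at format
boundaries.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .curve_fitting import (
    DirectFit,
    ModelComparison,
    compare_models,
    fit_exponential,
    fit_gompertz,
)
from .errors import DataError, FitError, MetagrowthError
from .formation_rate import RateFit, fit_formation_rate
from .formation_times import FormationEstimate, estimate_all_formations
from .growth_models import GrowthParameters
from .linearized_fit import (
    GENERAL_GOMPERTZ,
    ONE_CELL_VOLUME_CM3,
    HeterogeneousSummary,
    LinearizedFit,
    describe_heterogeneous,
    fit_sgr_logv,
)
from .sgr_estimation import IntervalEstimate, LesionSeries, VolumeMeasurement, all_intervals

__all__ = [
    "PatientDataset",
    "AnalysisConfig",
    "PatientReport",
    "read_measurements",
    "analyze_patient",
    "write_report",
    "report_to_dict",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
REQUIRED_COLUMNS = ("lesion_id", "time", "volume_cm3")


@dataclass(frozen=True)
class PatientDataset:
    """All lesion series of one patient, plus an optional calendar epoch
    mapping day 0 to a date (used only to print formation *years*)."""

    patient_id: str
    series: tuple[LesionSeries, ...]
    epoch: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.series:
            raise DataError(f"patient {self.patient_id!r}: no lesion series")
        ids = [s.lesion_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise DataError(f"patient {self.patient_id!r}: duplicate lesion ids")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters, echoed verbatim into every report.

    ``v0_assumed`` is the reference volume at which the regression's SGR0
    is quoted and the general curve is anchored; ``one_cell_volume`` is
    the back-extrapolation target for formation times.  Both default to
    1e-9 cm^3 (one cell) and normally coincide.
    """

    v0_assumed: float = ONE_CELL_VOLUME_CM3
    one_cell_volume: float = ONE_CELL_VOLUME_CM3
    alpha: float = 0.05
    indifference_margin: float = 0.02

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PatientReport:
    """Full pipeline output for one patient.

    ``skip_reasons`` records every stage or lesion that could not be
    processed and why — partial results are flagged, never silent.
    """

    patient_id: str
    config: AnalysisConfig
    linearized: LinearizedFit | None
    general_curve: GrowthParameters | None
    heterogeneous: HeterogeneousSummary | None
    direct_fits: tuple[DirectFit, ...]
    comparisons: tuple[ModelComparison, ...]
    formations: tuple[FormationEstimate, ...]
    formation_pathway: str | None
    rate: RateFit | None
    skip_reasons: tuple[str, ...]
    provenance: dict = field(default_factory=dict)


def _parse_times(raw: pd.Series, epoch: _dt.date | None) -> tuple[np.ndarray, _dt.date | None]:
    """Times as float days; ISO dates become days since the epoch
    (earliest date when no epoch is given)."""
    try:
        return raw.astype(float).to_numpy(), epoch
    except (ValueError, TypeError):
        pass
    try:
        dates = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DataError(
            f"'time' column is neither numeric days nor ISO dates: {exc}"
        ) from None
    if epoch is None:
        epoch = dates.min().date()
    origin = pd.Timestamp(epoch)
    return ((dates - origin) / pd.Timedelta(days=1)).to_numpy(), epoch


def read_measurements(
    path,
    sep: str | None = None,
    strict: bool = True,
    patient_id: str | None = None,
    epoch: _dt.date | None = None,
) -> PatientDataset:
    """Parse a measurement table into a validated patient dataset.

    The file is UTF-8 CSV or TSV (separator inferred from the extension
    unless given), header required, ``#`` comment lines ignored.  In
    strict mode non-positive volumes abort with the offending line number;
    in lenient mode they are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")

    times, epoch = _parse_times(df["time"], epoch)
    try:
        volumes = df["volume_cm3"].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: non-numeric volume ({exc})") from exc

    bad = ~(np.isfinite(volumes) & (volumes > 0.0))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        if strict:
            raise DataError(
                f"{path}: non-positive or non-finite volume_cm3 on line(s) "
                f"{', '.join(map(str, lines))} (strict mode)"
            )
        logger.warning("%s: dropped %d non-positive volume row(s)", path, bad.sum())
        df, times, volumes = df[~bad], times[~bad], volumes[~bad]

    series = []
    for lid, idx in df.groupby("lesion_id", sort=True).groups.items():
        loc = df.index.get_indexer(idx)
        ms = tuple(
            VolumeMeasurement(str(lid), float(times[i]), float(volumes[i])) for i in loc
        )
        series.append(LesionSeries(str(lid), ms))
    return PatientDataset(
        patient_id=patient_id or path.stem, series=tuple(series), epoch=epoch
    )


def _input_hash(dataset: PatientDataset) -> str:
    payload = json.dumps(
        [
            [s.lesion_id, [[m.t, m.v] for m in s.measurements]]
            for s in sorted(dataset.series, key=lambda s: s.lesion_id)
        ],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_patient(
    dataset: PatientDataset, config: AnalysisConfig | None = None
) -> PatientReport:
    """Run the full five-stage pipeline on one patient.

    Deterministic for a fixed dataset and config.  Stage failures are
    collected into ``skip_reasons`` with stage and lesion context; the
    linearized stage failing (too few intervals) still leaves the direct
    per-lesion fits in the report.
    """
    config = config or AnalysisConfig()
    skips: list[str] = []

    # Stages 1-2: interval records.
    intervals = all_intervals(dataset.series)

    # Stage 3: linearized regression + model selection.
    linearized: LinearizedFit | None = None
    try:
        linearized = fit_sgr_logv(intervals, v0_assumed=config.v0_assumed, alpha=config.alpha)
    except DataError as exc:
        skips.append(f"linearized: {exc}")

    heterogeneous: HeterogeneousSummary | None = None
    if intervals:
        heterogeneous = describe_heterogeneous(intervals)

    # Direct fits (always attempted, for the comparison table).
    direct_fits: list[DirectFit] = []
    comparisons: list[ModelComparison] = []
    exp_by_lesion: dict[str, DirectFit] = {}
    for s in dataset.series:
        try:
            e = fit_exponential(s, one_cell_volume=config.one_cell_volume)
            direct_fits.append(e)
            exp_by_lesion[s.lesion_id] = e
        except FitError as exc:
            skips.append(f"direct/exponential: {exc}")
            continue
        try:
            g = fit_gompertz(s, one_cell_volume=config.one_cell_volume)
            direct_fits.append(g)
            comparisons.append(compare_models(e, g, config.indifference_margin))
        except FitError as exc:
            skips.append(f"direct/gompertz: {exc}")

    # Stages 4-5: general curve, formation times, formation rate.
    general: GrowthParameters | None = None
    formations: list[FormationEstimate] = []
    pathway: str | None = None
    if linearized is not None:
        if linearized.selected_model == GENERAL_GOMPERTZ:
            pathway = GENERAL_GOMPERTZ
            general = GrowthParameters(
                sgr0=linearized.sgr0,
                lam=linearized.lam,
                v0=config.one_cell_volume,
                t0=0.0,
            )
            try:
                formations = estimate_all_formations(dataset.series, general)
            except MetagrowthError as exc:
                skips.append(f"formation/shift: {exc}")
        else:
            # Heterogeneous branch: each lesion dated by its own
            # exponential back-extrapolation.
            pathway = linearized.selected_model
            for s in dataset.series:
                e = exp_by_lesion.get(s.lesion_id)
                if e is None:
                    skips.append(
                        f"formation/exponential: lesion {s.lesion_id!r} has no exponential fit"
                    )
                    continue
                if not math.isfinite(e.formation_time):
                    skips.append(
                        f"formation/exponential: lesion {s.lesion_id!r} has non-positive "
                        "growth, no finite formation time"
                    )
                    continue
                formations.append(
                    FormationEstimate(
                        lesion_id=s.lesion_id,
                        formation_t=e.formation_time,
                        sse=e.sse,
                        n_points=e.n_points,
                    )
                )
            formations.sort(key=lambda f: (f.formation_t, f.lesion_id))

    rate: RateFit | None = None
    if len(formations) >= 2:
        try:
            rate = fit_formation_rate(formations)
        except DataError as exc:
            skips.append(f"rate: {exc}")
    elif formations:
        skips.append("rate: needs >= 2 dated lesions")

    return PatientReport(
        patient_id=dataset.patient_id,
        config=config,
        linearized=linearized,
        general_curve=general,
        heterogeneous=heterogeneous,
        direct_fits=tuple(direct_fits),
        comparisons=tuple(comparisons),
        formations=tuple(formations),
        formation_pathway=pathway,
        rate=rate,
        skip_reasons=tuple(skips),
        provenance={
            "schema_version": SCHEMA_VERSION,
            "package_version": __version__,
            "input_hash": _input_hash(dataset),
            "epoch": dataset.epoch.isoformat() if dataset.epoch else None,
            "config": config.to_dict(),
        },
    )


def _day_to_year(day: float, epoch: _dt.date | None) -> int | None:
    """Calendar year of an absolute day offset, when an epoch is known."""
    if epoch is None or not math.isfinite(day):
        return None
    return (pd.Timestamp(epoch) + pd.Timedelta(days=round(day))).year


def _nan_to_none(x: float) -> float | None:
    return None if (isinstance(x, float) and math.isnan(x)) else x


def report_to_dict(report: PatientReport) -> dict:
    """Loss-less JSON-serialisable form of a report."""
    epoch = None
    if report.provenance.get("epoch"):
        epoch = _dt.date.fromisoformat(report.provenance["epoch"])

    def fits():
        for f in report.direct_fits:
            d = dataclasses.asdict(f)
            d["params"] = dataclasses.asdict(f.params)
            d["formation_time"] = _nan_to_none(f.formation_time)
            d["formation_year"] = _day_to_year(f.formation_time, epoch)
            yield d

    out = {
        "patient_id": report.patient_id,
        "linearized": dataclasses.asdict(report.linearized) if report.linearized else None,
        "general_curve": dataclasses.asdict(report.general_curve)
        if report.general_curve
        else None,
        "heterogeneous": dataclasses.asdict(report.heterogeneous)
        if report.heterogeneous
        else None,
        "direct_fits": list(fits()),
        "comparisons": [
            {
                **dataclasses.asdict(c),
                "formation_exponential": _nan_to_none(c.formation_exponential),
                "formation_gompertz": _nan_to_none(c.formation_gompertz),
                "formation_gap_days": _nan_to_none(c.formation_gap_days),
            }
            for c in report.comparisons
        ],
        "formations": [
            {**dataclasses.asdict(f), "formation_year": _day_to_year(f.formation_t, epoch)}
            for f in report.formations
        ],
        "formation_pathway": report.formation_pathway,
        "rate": dataclasses.asdict(report.rate) if report.rate else None,
        "skip_reasons": list(report.skip_reasons),
        "provenance": report.provenance,
    }
    # normalise containers (tuples -> lists) so the dict equals its own
    # JSON round-trip
    return json.loads(json.dumps(out))


def _summary_rows(report: PatientReport) -> pd.DataFrame:
    """Per-(lesion, model) summary mirroring the classic results-table
    layout, with SGR printed in %/day."""
    epoch = None
    if report.provenance.get("epoch"):
        epoch = _dt.date.fromisoformat(report.provenance["epoch"])
    rows = []
    for f in report.direct_fits:
        year = _day_to_year(f.formation_time, epoch)
        rows.append(
            {
                "lesion": f.lesion_id,
                "model": f.model,
                "n": f.n_points,
                "sgr0_pct_per_day": f"{100.0 * f.sgr_at_formation:.2g}",
                "lambda_per_day": f"{f.params.lam:.2g}",
                "formation_day": ""
                if math.isnan(f.formation_time)
                else f"{f.formation_time:.1f}",
                "formation_year": "" if year is None else str(year),
                "r2": f"{f.r2:.3f}",
            }
        )
    lin = report.linearized
    rows.append(
        {
            "lesion": "PATIENT",
            "model": lin.selected_model if lin else "unresolved",
            "n": lin.n_points if lin else 0,
            "sgr0_pct_per_day": f"{100.0 * lin.sgr0:.2g}" if lin else "",
            "lambda_per_day": f"{lin.lam:.2g}" if lin else "",
            "formation_day": f"{report.rate.t_first:.1f}" if report.rate else "",
            "formation_year": "",
            "r2": f"{lin.r2:.3f}" if lin else "",
        }
    )
    return pd.DataFrame(rows)


def write_report(report: PatientReport, path, fmt: str = "json") -> None:
    """Serialise a report: loss-less schema-versioned JSON, or a TSV
    summary with one row per (lesion, model) and a patient footer row."""
    path = Path(path)
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        _summary_rows(report).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r} (expected 'json' or 'tsv')")
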