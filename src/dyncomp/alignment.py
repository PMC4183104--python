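"""Event-aligned order-transition analysis.

Each patient's trajectories are re-anchored so that the onset of exposure
with response prevention (ERP) is relative day 0 (negative = before onset).
Outcome series are z-transformed within patient so trajectories are
comparable across patients, averaged on a common half-weekly grid, and the
order transition is located as the steepest (most negative) change between
consecutive assessments.  The directional hypothesis of interest is whether
that steepest drop falls *before* day 0, i.e. before the major intervention.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import EventMetadata, OutcomeSeries

__all__ = [
    "AlignedSeries",
    "GradientReport",
    "PairedTestReport",
    "ztransform",
    "align_to_event",
    "align_cohort",
    "steepest_gradient",
    "group_mean_curve",
    "phase_elevation_test",
]

logger = logging.getLogger(__name__)


@dataclass
class AlignedSeries:
    """Values on a relative-day axis with 0 at the patient's ERP onset."""

    patient_id: str
    relative_days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.relative_days = np.asarray(self.relative_days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.relative_days) <= 0):
            raise ValueError(f"relative days must be strictly increasing ({self.patient_id})")


@dataclass
class GradientReport:
    """Location and size of the steepest consecutive-assessment change."""

    patient_id: str
    steepest_interval: tuple[int, int]  # (day_a, day_b), consecutive assessments
    gradient: float  # most negative successive difference (raw score change)
    location_vs_event: int | None  # day_b in relative time, None if unaligned
    improving: bool  # gradient < 0


@dataclass
class PairedTestReport:
    t: float
    df: int
    p: float
    d_z: float  # Cohen's d for paired differences
    mean_difference: float
    n: int


def ztransform(series: OutcomeSeries) -> np.ndarray:
    """Within-patient z-scores of the outcome values (sd with n-1 denominator)."""
    if len(series) < 2:
        raise ValueError(f"need >=2 assessments to z-transform (patient {series.patient_id})")
    sd = series.scores.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance in outcome of patient {series.patient_id}")
    return (series.scores - series.scores.mean()) / sd


def align_to_event(
    series: OutcomeSeries | AlignedSeries,
    event: EventMetadata,
    values: np.ndarray | None = None,
) -> AlignedSeries:
    """Shift a patient's day axis so the ERP onset becomes relative day 0.

    ``values`` optionally replaces the series' own values (e.g. z-scores).
    An onset outside the observed span only warns; a missing onset raises —
    cohort-level handling of non-participants lives in :func:`align_cohort`.
    """
    if event.erp_onset_day is None:
        raise ValueError(f"patient {event.patient_id} has no ERP onset")
    days = series.days if isinstance(series, OutcomeSeries) else series.relative_days
    vals = values if values is not None else (
        series.scores if isinstance(series, OutcomeSeries) else series.values
    )
    if not (days.min() <= event.erp_onset_day <= days.max()):
        logger.warning(
            "ERP onset day %d outside observed span for patient %s; aligning anyway",
            event.erp_onset_day, event.patient_id,
        )
    return AlignedSeries(
        patient_id=event.patient_id,
        relative_days=days - event.erp_onset_day,
        values=np.asarray(vals, dtype=float),
    )


def align_cohort(
    series_list: list[OutcomeSeries],
    events: list[EventMetadata],
    z: bool = True,
) -> tuple[list[AlignedSeries], list[str]]:
    """Align every ERP participant; return aligned series plus excluded patient ids.

    Patients without an ERP onset are excluded with a logged reason (the
    analysis runs on the ERP subsample only).
    """
    by_pid = {e.patient_id: e for e in events}
    aligned: list[AlignedSeries] = []
    excluded: list[str] = []
    for s in series_list:
        event = by_pid.get(s.patient_id)
        if event is None or event.erp_onset_day is None:
            excluded.append(s.patient_id)
            logger.info("patient %s excluded from ERP alignment (no onset)", s.patient_id)
            continue
        vals = ztransform(s) if z else s.scores
        aligned.append(align_to_event(s, event, values=vals))
    return aligned, excluded


def steepest_gradient(series: OutcomeSeries | AlignedSeries) -> GradientReport:
    """Most negative change between consecutive assessments (ties -> earliest).

    Assessments are near-equidistant (about twice per week), so the raw
    successive difference is the gradient unit.  A monotone increasing series
    still returns its smallest increase, flagged as non-improving.
    """
    if isinstance(series, AlignedSeries):
        days, vals, rel = series.relative_days, series.values, True
    else:
        days, vals, rel = series.days, series.scores, False
    if days.size < 2:
        raise ValueError(f"need >=2 assessments (patient {series.patient_id})")
    diffs = np.diff(vals)
    k = int(np.argmin(diffs))  # argmin returns the first (earliest) minimum
    day_a, day_b = int(days[k]), int(days[k + 1])
    return GradientReport(
        patient_id=series.patient_id,
        steepest_interval=(day_a, day_b),
        gradient=float(diffs[k]),
        location_vs_event=day_b if rel else None,
        improving=bool(diffs[k] < 0),
    )


def group_mean_curve(
    aligned: list[AlignedSeries],
    grid_step: float = 3.5,
    snap_tolerance: float = 2.0,
    min_n: int = 2,
) -> pd.DataFrame:
    """Cross-patient mean +/- sd on a common relative-day grid anchored at 0.

    Assessment days do not coincide across patients, so each patient
    contributes to a grid point the value of their nearest assessment within
    ``snap_tolerance`` days (else they are omitted from that point).  Grid
    points are multiples of ``grid_step`` (half-weekly by default); points to
    which fewer than ``min_n`` patients contribute are not reported.  Returns
    a DataFrame with columns relative_day, mean, sd, n.
    """
    if not aligned:
        raise ValueError("no aligned series supplied")
    lo = min(s.relative_days.min() for s in aligned)
    hi = max(s.relative_days.max() for s in aligned)
    grid = np.arange(np.floor(lo / grid_step), np.ceil(hi / grid_step) + 1) * grid_step
    rows = []
    for g in grid:
        contrib = []
        for s in aligned:
            dist = np.abs(s.relative_days - g)
            k = int(np.argmin(dist))
            if dist[k] <= snap_tolerance and not np.isnan(s.values[k]):
                contrib.append(s.values[k])
        if len(contrib) >= min_n:
            arr = np.asarray(contrib)
            rows.append(
                {
                    "relative_day": g,
                    "mean": arr.mean(),
                    "sd": arr.std(ddof=1) if arr.size > 1 else np.nan,
                    "n": arr.size,
                }
            )
    return pd.DataFrame(rows, columns=["relative_day", "mean", "sd", "n"])


def phase_elevation_test(
    in_window: np.ndarray, reference: np.ndarray
) -> PairedTestReport:
    """Paired two-sided t-test of per-patient in-window means vs reference means.

    Used both for complexity elevation inside candidate instability windows
    (vs the mean complexity outside them) and for symptom level at ERP onset
    (vs the pre-transition level).  Cohen's d_z = mean(diff) / sd(diff).
    """
    a = np.asarray(in_window, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    n = a.size
    if n < 2:
        raise ValueError("need >=2 complete pairs")
    diffs = a - b
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.all(diffs == 0):  # identical pairs: no effect, not degenerate
            return PairedTestReport(t=0.0, df=n - 1, p=1.0, d_z=0.0,
                                    mean_difference=0.0, n=n)
        raise ValueError("zero variance of paired differences (degenerate t)")
    res = stats.ttest_rel(a, b)
    return PairedTestReport(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        d_z=float(diffs.mean() / sd),
        mean_difference=float(diffs.mean()),
        n=n,
    )
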