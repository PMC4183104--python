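"""Detection of critical-instability phases from dynamic-complexity series.

A phase of critical instability is a run of days whose dynamic complexity is
significantly elevated relative to the series' own whole-timeframe
distribution.  "Significant" is operationalized as a one-sided z-threshold:
day t is flagged when (C_t - mean(C)) / sd(C) exceeds the standard-normal
critical value for the chosen alpha (1.645 at alpha = 0.05).  No population
norms exist for these ratings, so the series is its own reference; no
multiple-testing correction is applied across days or items (deliberately
liberal, matching how the threshold is used in practice).

The patient-level instability intensity is the max-minus-mean complexity
score: local peaks matter, not the average complexity level.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import stats

from .complexity import ComplexityMatrix, ComplexitySeries, mean_complexity_curve

__all__ = [
    "InstabilityMask",
    "InstabilityProfile",
    "InstabilityScore",
    "PeakTestReport",
    "instability_mask",
    "instability_frequency",
    "frequency_peak_test",
    "max_mean_score",
    "detect_phases",
    "build_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class InstabilityMask:
    item_id: str
    days: np.ndarray
    flags: np.ndarray  # boolean; False wherever complexity undefined
    defined: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.flags & ~self.defined):
            raise ValueError("flagged days must be a subset of defined days")


@dataclass
class InstabilityProfile:
    patient_id: str
    masks: list[InstabilityMask]
    days: np.ndarray
    frequency: np.ndarray  # percent of defined items flagged, per day
    phases: list[tuple[int, int]]  # inclusive (start_day, end_day) in anchor days


@dataclass
class InstabilityScore:
    patient_id: str
    per_item: dict[str, float]
    score: float


@dataclass
class PeakTestReport:
    t: float
    df: int
    p: float
    window_mean: float
    overall_mean: float
    sd: float
    orientation: str


def _z_threshold(alpha: float) -> float:
    if not (0.0 < alpha <= 0.5):
        raise ValueError(f"alpha must lie in (0, 0.5], got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha))


def _elevated(values: np.ndarray, alpha: float) -> np.ndarray:
    """One-sided z-rule flags against the series' own defined values."""
    crit = _z_threshold(alpha)
    defined = ~np.isnan(values)
    flags = np.zeros(values.size, dtype=bool)
    vals = values[defined]
    if vals.size < 2:
        return flags
    sd = vals.std(ddof=1)
    if sd == 0:
        return flags
    z = (values - vals.mean()) / sd
    flags[defined] = z[defined] > crit
    return flags


def instability_mask(cs: ComplexitySeries, alpha: float = 0.05) -> InstabilityMask:
    """Flag anchor days with significantly elevated complexity for one item."""
    flags = _elevated(cs.C_values, alpha)
    return InstabilityMask(item_id=cs.item_id, days=cs.days, flags=flags, defined=cs.defined)


def instability_frequency(masks: list[InstabilityMask]) -> tuple[np.ndarray, np.ndarray]:
    """Per-day percentage of items (with defined complexity) that are flagged."""
    if not masks:
        raise ValueError("no masks supplied")
    axes = {tuple(m.days) for m in masks}
    if len(axes) > 1:
        raise ValueError("masks must share a day axis")
    days = masks[0].days
    flagged = np.sum([m.flags for m in masks], axis=0).astype(float)
    defined = np.sum([m.defined for m in masks], axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(defined > 0, 100.0 * flagged / defined, np.nan)
    return days, freq


def frequency_peak_test(
    days: np.ndarray,
    freq: np.ndarray,
    candidate_window: tuple[int, int],
    orientation: str = "window",
) -> PeakTestReport:
    """Test whether instability frequency inside a candidate window is elevated.

    ``orientation='window'``: one-sample t of in-window daily frequencies
    against the whole-process mean frequency (df = n_window - 1).
    ``orientation='days'``: two-sample t of window days vs all other days
    (df = n_days - 2), the orientation consistent with degrees of freedom on
    the order of the series length.
    """
    days = np.asarray(days)
    freq = np.asarray(freq, dtype=float)
    lo, hi = candidate_window
    in_win = (days >= lo) & (days <= hi) & ~np.isnan(freq)
    out_win = ~((days >= lo) & (days <= hi)) & ~np.isnan(freq)
    win_vals = freq[in_win]
    if win_vals.size < 2:
        raise ValueError("candidate window must contain at least 2 defined days")
    overall = freq[~np.isnan(freq)]
    overall_mean = float(overall.mean())

    if orientation == "window":
        if win_vals.std(ddof=1) == 0:
            raise ValueError("degenerate input: zero variance inside the candidate window")
        res = stats.ttest_1samp(win_vals, popmean=overall_mean)
        t, p, df = float(res.statistic), float(res.pvalue), win_vals.size - 1
        sd = float(win_vals.std(ddof=1))
    elif orientation == "days":
        rest = freq[out_win]
        if rest.size < 2:
            raise ValueError("too few days outside the candidate window")
        if win_vals.std(ddof=1) == 0 and rest.std(ddof=1) == 0:
            raise ValueError("degenerate input: zero variance on both sides")
        res = stats.ttest_ind(win_vals, rest, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
        df = win_vals.size + rest.size - 2
        sd = float(np.concatenate([win_vals, rest]).std(ddof=1))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return PeakTestReport(
        t=t, df=df, p=p, window_mean=float(win_vals.mean()),
        overall_mean=overall_mean, sd=sd, orientation=orientation,
    )


def max_mean_score(matrix: ComplexityMatrix, variant: str = "per_item") -> InstabilityScore:
    """Max-minus-mean complexity: the intensity of local instability peaks.

    ``per_item`` (default): max(C) - mean(C) per item over its defined values,
    then averaged across items.  ``mean_curve``: the same difference computed
    on the patient's mean complexity curve.
    """
    if variant == "mean_curve":
        _, curve = mean_complexity_curve(matrix)
        vals = curve[~np.isnan(curve)]
        if vals.size == 0:
            raise ValueError("mean complexity curve has no defined values")
        s = float(vals.max() - vals.mean())
        return InstabilityScore(matrix.patient_id, {"mean_curve": s}, s)
    if variant != "per_item":
        raise ValueError(f"unknown variant {variant!r}")
    per_item: dict[str, float] = {}
    for item, row in zip(matrix.item_ids, matrix.C):
        vals = row[~np.isnan(row)]
        if vals.size == 0:
            logger.warning(
                "item %s of patient %s has no defined complexity values; excluded",
                item, matrix.patient_id,
            )
            continue
        per_item[item] = float(vals.max() - vals.mean())
    if not per_item:
        raise ValueError(f"no item with defined complexity for patient {matrix.patient_id}")
    return InstabilityScore(
        patient_id=matrix.patient_id,
        per_item=per_item,
        score=float(np.mean(list(per_item.values()))),
    )


def detect_phases(
    days: np.ndarray, curve: np.ndarray, alpha: float = 0.05
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive days whose curve value is significantly elevated.

    The same one-sided z-rule as :func:`instability_mask`, applied to any
    per-day curve (instability frequency or mean complexity).  Returns
    ordered, non-overlapping inclusive (start_day, end_day) intervals.
    """
    days = np.asarray(days)
    curve = np.asarray(curve, dtype=float)
    flags = _elevated(curve, alpha)
    phases: list[tuple[int, int]] = []
    i = 0
    n = flags.size
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1] and days[j + 1] == days[j] + 1:
                j += 1
            phases.append((int(days[i]), int(days[j])))
            i = j + 1
        else:
            i += 1
    return phases


def build_profile(
    matrix: ComplexityMatrix, alpha: float = 0.05, phase_source: str = "frequency"
) -> InstabilityProfile:
    """Masks, cross-item frequency distribution, and phases for one patient.

    ``phase_source`` chooses the curve the phase rule runs on: the cross-item
    instability frequency (default) or the mean complexity curve.
    """
    rows = [
        ComplexitySeries(matrix.patient_id, item, matrix.days,
                         np.full_like(row, np.nan), np.full_like(row, np.nan), row)
        for item, row in zip(matrix.item_ids, matrix.C)
    ]
    masks = [instability_mask(cs, alpha) for cs in rows]
    days, freq = instability_frequency(masks)
    if phase_source == "frequency":
        phases = detect_phases(days, freq, alpha)
    elif phase_source == "mean_complexity":
        _, curve = mean_complexity_curve(matrix)
        phases = detect_phases(days, curve, alpha)
    else:
        raise ValueError(f"unknown phase_source {phase_source!r}")
    return InstabilityProfile(
        patient_id=matrix.patient_id, masks=masks, days=days, frequency=freq, phases=phases
    )
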