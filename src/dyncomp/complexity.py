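"""Dynamic complexity of short, coarse-grained, bounded-scale time series.

Dynamic complexity C is the product of a fluctuation measure F and a
distribution measure D, evaluated in a moving window (default width 7 days)
over each item's daily trajectory.  It was designed for exactly the kind of
data a daily therapy-monitoring questionnaire produces: short series
(a few dozen points), coarse ordinal scales, no distributional assumptions.

* F captures the amplitude and frequency of direction changes inside the
  window, normalized so that a constant window scores 0 and a min/max
  alternation at every step scores 1.
* D captures how evenly the window's values cover the full scale range:
  0 for zero scatter, 1 when the sorted values are exactly uniformly spread
  over the whole scale.

Both are scale-affine invariant and time-reversal invariant, and C = F*D
always lies in [0, 1].  Windows containing missing values yield NaN
("undefined"), never 0 — zero means stability, not absence of data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_data import RatingScale, RatingSeries

__all__ = [
    "ComplexityParams",
    "ComplexitySeries",
    "ComplexityMatrix",
    "fluctuation_measure",
    "distribution_measure",
    "complexity_series",
    "complexity_matrix",
    "mean_complexity_curve",
]


@dataclass(frozen=True)
class ComplexityParams:
    """Moving-window parameters.

    ``window_width`` is the number of consecutive daily points per window
    (7 by default); ``min_series_length`` is the validity floor below which a
    series is considered too short for a meaningful complexity trajectory
    (20 points by default).
    """

    window_width: int = 7
    min_series_length: int = 20

    def __post_init__(self) -> None:
        if self.window_width < 3:
            raise ValueError("window_width must be >= 3")
        if self.min_series_length < self.window_width:
            raise ValueError("min_series_length must be >= window_width")


@dataclass
class ComplexitySeries:
    """F, D, C trajectories for one item; NaN flags undefined windows.

    ``days`` holds the window anchors: the anchor is the *first* day of the
    window, so value t summarizes days t .. t+m-1.
    """

    patient_id: str
    item_id: str
    days: np.ndarray
    F_values: np.ndarray
    D_values: np.ndarray
    C_values: np.ndarray

    def __len__(self) -> int:
        return int(self.days.size)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.C_values)


@dataclass
class ComplexityMatrix:
    """Items x anchor-days grid of C values (the complexity resonance diagram)."""

    patient_id: str
    item_ids: list[str]
    days: np.ndarray
    C: np.ndarray  # shape (n_items, n_anchors), NaN = undefined

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.item_ids), self.days.size):
            raise ValueError("C shape must be (n_items, n_anchor_days)")

    def row(self, item_id: str) -> np.ndarray:
        return self.C[self.item_ids.index(item_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.C, index=self.item_ids, columns=self.days)


# ---------------------------------------------------------------------------
# Window measures
# ---------------------------------------------------------------------------

def _turning_points(window: np.ndarray) -> list[int]:
    """Indices of turning points: both endpoints plus every local extremum.

    The window is compressed into runs of equal consecutive values.  An
    interior run whose neighbours lie on the same side (a peak or a trough,
    possibly flat) contributes a turning point at *both* of its ends, which
    keeps F exactly time-reversal invariant; plateaus inside a monotone run
    and terminal plateaus are absorbed into the surrounding segment.
    """
    m = window.size
    # run-length encode
    starts = [0]
    for k in range(1, m):
        if window[k] != window[k - 1]:
            starts.append(k)
    ends = [s - 1 for s in starts[1:]] + [m - 1]
    tps = {0, m - 1}
    for r in range(1, len(starts) - 1):
        prev_val = window[starts[r - 1]]
        val = window[starts[r]]
        next_val = window[starts[r + 1]]
        if (val - prev_val) * (next_val - val) < 0:  # flat or sharp extremum
            tps.add(starts[r])
            tps.add(ends[r])
    return sorted(tps)


def fluctuation_measure(window: np.ndarray, scale: RatingScale) -> float:
    """Fluctuation F in [0, 1]: summed |slope| between successive turning points,
    normalized by the maximal possible fluctuation R*(m-1).

    Returns NaN when the window contains a missing value.
    """
    window = np.asarray(window, dtype=float)
    m = window.size
    if m < 3:
        raise ValueError("window must contain at least 3 points")
    if np.isnan(window).any():
        return float("nan")
    _check_in_scale(window, scale)
    tps = _turning_points(window)
    total = 0.0
    for a, b in zip(tps[:-1], tps[1:]):
        total += abs(window[b] - window[a]) / (b - a)
    return total / (scale.range * (m - 1))


def distribution_measure(window: np.ndarray, scale: RatingScale) -> float:
    """Distribution D in [0, 1]: evenness of scale coverage.

    With the window sorted ascending, each pair (i < j) has an ideal
    separation I_ij = (j-i) * R / (m-1) under perfectly uniform coverage of
    the full range; only shortfalls below the ideal (clustering) are
    penalized: D = 1 - sum(max(0, I-A)) / sum(I).
    """
    window = np.asarray(window, dtype=float)
    if window.size < 3:
        raise ValueError("window must contain at least 3 points")
    if np.isnan(window).any():
        return float("nan")
    _check_in_scale(window, scale)
    return float(_distribution_bulk(window[None, :], scale.range)[0])


def _check_in_scale(window: np.ndarray, scale: RatingScale) -> None:
    if scale.range <= 0:
        raise ValueError("scale range must be positive")
    if window.min() < scale.min_value or window.max() > scale.max_value:
        raise ValueError("window values outside the declared scale")


def _distribution_bulk(windows: np.ndarray, R: float) -> np.ndarray:
    """Vectorized D over an array of complete windows, shape (k, m)."""
    m = windows.shape[1]
    srt = np.sort(windows, axis=1)
    i_idx, j_idx = np.triu_indices(m, k=1)
    ideal = (j_idx - i_idx) * (R / (m - 1))
    actual = srt[:, j_idx] - srt[:, i_idx]
    deficit = np.clip(ideal - actual, 0.0, None).sum(axis=1)
    return 1.0 - deficit / ideal.sum()


# ---------------------------------------------------------------------------
# Moving-window series and matrices
# ---------------------------------------------------------------------------

def complexity_series(
    series: RatingSeries, params: ComplexityParams = ComplexityParams()
) -> ComplexitySeries:
    """Slide the window over one item's trajectory and return F, D, C series.

    The series must meet the >=20-point validity floor.  Day indices must be
    contiguous (daily sampling); windows touching a missing value give NaN.
    """
    n = len(series)
    if n < params.min_series_length:
        raise ValueError(
            f"series of length {n} is below the validity floor of "
            f"{params.min_series_length} measurement points "
            f"(patient {series.patient_id}, item {series.item_id})"
        )
    if np.any(np.diff(series.days) != 1):
        raise ValueError(
            "complexity requires daily (contiguous) day indices; "
            f"gaps present for patient {series.patient_id}, item {series.item_id}"
        )
    m = params.window_width
    wins = sliding_window_view(series.values, m)
    anchors = series.days[: n - m + 1]
    complete = ~np.isnan(wins).any(axis=1)

    F = np.full(wins.shape[0], np.nan)
    D = np.full(wins.shape[0], np.nan)
    if complete.any():
        R = series.scale.range
        D[complete] = _distribution_bulk(wins[complete], R)
        denom = R * (m - 1)
        for idx in np.nonzero(complete)[0]:
            w = wins[idx]
            tps = _turning_points(w)
            total = 0.0
            for a, b in zip(tps[:-1], tps[1:]):
                total += abs(w[b] - w[a]) / (b - a)
            F[idx] = total / denom
    return ComplexitySeries(
        patient_id=series.patient_id,
        item_id=series.item_id,
        days=anchors,
        F_values=F,
        D_values=D,
        C_values=F * D,
    )


def complexity_matrix(
    series_set: list[RatingSeries],
    params: ComplexityParams = ComplexityParams(),
    item_order: list[str] | None = None,
) -> ComplexityMatrix:
    """Stack per-item complexity series of one patient into an items x days matrix."""
    if not series_set:
        raise ValueError("no series supplied")
    pids = {s.patient_id for s in series_set}
    if len(pids) > 1:
        raise ValueError(f"complexity matrix mixes patients {pids}")
    axes = {tuple(s.days) for s in series_set}
    if len(axes) > 1:
        raise ValueError("all item series must share the patient's day axis")
    by_item = {s.item_id: s for s in series_set}
    order = item_order if item_order is not None else [s.item_id for s in series_set]
    missing = [i for i in order if i not in by_item]
    if missing:
        raise ValueError(f"item_order names absent items: {missing}")
    rows = [complexity_series(by_item[item], params) for item in order]
    return ComplexityMatrix(
        patient_id=series_set[0].patient_id,
        item_ids=list(order),
        days=rows[0].days,
        C=np.vstack([r.C_values for r in rows]),
    )


def mean_complexity_curve(
    matrix: ComplexityMatrix | np.ndarray, days: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Available-case mean of C over items (rows) per anchor day.

    Accepts a ComplexityMatrix or a raw 2-D array plus its day axis; days on
    which no item has a defined value come back NaN.
    """
    if isinstance(matrix, ComplexityMatrix):
        C, days = matrix.C, matrix.days
    else:
        C = np.asarray(matrix, dtype=float)
        if days is None:
            raise ValueError("days axis required with a raw array")
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(C), axis=0)
        mean = np.where(counts > 0, np.nansum(np.where(np.isnan(C), 0.0, C), axis=0), np.nan)
        mean = np.where(counts > 0, mean / np.maximum(counts, 1), np.nan)
    return np.asarray(days), mean
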