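"""Data model, validation, factor scoring, and file I/O for daily process ratings.

The analysis operates on three kinds of input per patient:

* daily self-ratings on a bounded ordinal scale (one value per item per day),
  e.g. the 47 items of the Therapy Process Questionnaire (TPQ) grouped into
  five factors;
* a sparser outcome series (Y-BOCS totals, 0-40, collected about twice per
  week);
* event metadata (day of exposure-with-response-prevention onset, treatment
  start and end).

Day indices are integers, 0-based from each patient's first rating day.
Missing ratings are carried as NaN, never dropped, so that downstream
moving-window statistics can flag windows contaminated by missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RatingScale",
    "RatingSeries",
    "FactorMap",
    "OutcomeSeries",
    "EventMetadata",
    "load_ratings",
    "write_ratings",
    "load_outcomes",
    "write_outcomes",
    "load_events",
    "write_events",
    "load_factor_config",
    "write_factor_config",
    "impute_short_gaps",
    "factor_score_series",
    "patient_mean_level",
]


class RatingsValidationError(ValueError):
    """Raised when an input table violates the declared data contract."""


@dataclass(frozen=True)
class RatingScale:
    """Bounds of the ordinal rating scale; its range R normalizes F and D."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if not self.max_value > self.min_value:
            raise ValueError(
                f"scale max_value ({self.max_value}) must exceed min_value ({self.min_value})"
            )

    @property
    def range(self) -> float:
        return self.max_value - self.min_value

    def contains(self, value: float) -> bool:
        return self.min_value <= value <= self.max_value


@dataclass
class RatingSeries:
    """One patient's daily trajectory for one item (NaN marks missing days)."""

    patient_id: str
    item_id: str
    days: np.ndarray
    values: np.ndarray
    scale: RatingScale

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.size < 1:
            raise ValueError("RatingSeries must contain at least one day")
        if self.days.size != self.values.size:
            raise ValueError("days and values must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(
                f"days must be strictly increasing (patient {self.patient_id}, item {self.item_id})"
            )
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (
            observed.min() < self.scale.min_value or observed.max() > self.scale.max_value
        ):
            raise ValueError(
                f"values outside scale [{self.scale.min_value}, {self.scale.max_value}] "
                f"(patient {self.patient_id}, item {self.item_id})"
            )

    def __len__(self) -> int:
        return int(self.days.size)

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


@dataclass
class FactorMap:
    """Assignment of items to factors plus the designated analysis roles.

    ``motivation_item`` plays the control-parameter role, ``symptom_factor``
    is the complaints/symptom-severity factor used for the process-based
    outcome, and ``boundary_factors`` are the interpersonal-stability factors
    (ward atmosphere, therapeutic relationship).
    """

    factors: dict[str, list[str]]
    motivation_item: str
    symptom_factor: str
    boundary_factors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fid, items in self.factors.items():
            for item in items:
                if item in seen:
                    raise ValueError(
                        f"item {item!r} assigned to both factor {seen[item]!r} and {fid!r}"
                    )
                seen[item] = fid
        if self.motivation_item not in seen:
            raise ValueError(f"motivation item {self.motivation_item!r} not in any factor")
        for fid in [self.symptom_factor, *self.boundary_factors]:
            if fid not in self.factors:
                raise ValueError(f"designated factor {fid!r} not present in factor map")

    @property
    def item_ids(self) -> list[str]:
        return [item for items in self.factors.values() for item in items]

    def factor_of(self, item_id: str) -> str | None:
        for fid, items in self.factors.items():
            if item_id in items:
                return fid
        return None


@dataclass
class OutcomeSeries:
    """Sparse outcome assessments (Y-BOCS totals on 0-40) for one patient."""

    patient_id: str
    days: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.days.size != self.scores.size:
            raise ValueError("days and scores must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"outcome days must be increasing (patient {self.patient_id})")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 40):
            raise ValueError(f"Y-BOCS scores must lie in [0, 40] (patient {self.patient_id})")

    def __len__(self) -> int:
        return int(self.days.size)


@dataclass(frozen=True)
class EventMetadata:
    """Per-patient treatment events; ERP onset may be absent (non-participant)."""

    patient_id: str
    treatment_start_day: int
    treatment_end_day: int
    erp_onset_day: int | None = None

    def __post_init__(self) -> None:
        if self.treatment_end_day < self.treatment_start_day:
            raise ValueError(f"treatment ends before it starts (patient {self.patient_id})")
        if self.erp_onset_day is not None and not (
            self.treatment_start_day <= self.erp_onset_day <= self.treatment_end_day
        ):
            raise ValueError(
                f"ERP onset outside treatment interval (patient {self.patient_id})"
            )


# ---------------------------------------------------------------------------
# File I/O (long-format CSVs; empty value field = missing)
# ---------------------------------------------------------------------------

def load_ratings(
    path: str | Path,
    scales: RatingScale | dict[str, RatingScale],
) -> list[RatingSeries]:
    """Read a long-format ratings CSV into one :class:`RatingSeries` per (patient, item).

    The file must have columns ``patient_id, day, item_id, value``; an empty
    value field marks a missing rating.  Out-of-range values and duplicate
    (patient, item, day) keys are errors, not silent fixes.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "item_id": str})
    required = {"patient_id", "day", "item_id", "value"}
    if not required.issubset(df.columns):
        raise RatingsValidationError(
            f"ratings file {path} missing columns {sorted(required - set(df.columns))}"
        )
    bad_day = df["day"].isna() | (df["day"].astype(float) % 1 != 0)
    if bad_day.any():
        row = int(df.index[bad_day][0]) + 2  # header + 1-based
        raise RatingsValidationError(f"malformed day index at row {row} of {path}")
    df["day"] = df["day"].astype(int)
    dupes = df.duplicated(["patient_id", "item_id", "day"], keep=False)
    if dupes.any():
        key = df.loc[dupes, ["patient_id", "item_id", "day"]].iloc[0]
        raise RatingsValidationError(
            f"duplicate rating for patient={key.patient_id!r} item={key.item_id!r} day={key.day}"
        )

    out: list[RatingSeries] = []
    for (pid, item), grp in df.groupby(["patient_id", "item_id"], sort=True):
        scale = scales[item] if isinstance(scales, dict) else scales
        grp = grp.sort_values("day")
        values = grp["value"].to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if observed.size and not all(scale.contains(v) for v in observed):
            bad = grp.loc[~grp["value"].apply(lambda v: np.isnan(v) or scale.contains(v))]
            day = int(bad["day"].iloc[0])
            raise RatingsValidationError(
                f"value outside scale [{scale.min_value}, {scale.max_value}] for "
                f"patient={pid!r} item={item!r} day={day}"
            )
        out.append(RatingSeries(pid, item, grp["day"].to_numpy(), values, scale))
    return out


def write_ratings(series_list: list[RatingSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for day, value in zip(s.days, s.values):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "day": int(day),
                    "item_id": s.item_id,
                    "value": "" if np.isnan(value) else value,
                }
            )
    pd.DataFrame(rows, columns=["patient_id", "day", "item_id", "value"]).to_csv(
        path, index=False
    )


def load_outcomes(path: str | Path) -> list[OutcomeSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        OutcomeSeries(pid, grp.sort_values("day")["day"].to_numpy(),
                      grp.sort_values("day")["ybocs_total"].to_numpy())
        for pid, grp in df.groupby("patient_id", sort=True)
    ]


def write_outcomes(series_list: list[OutcomeSeries], path: str | Path) -> None:
    rows = [
        {"patient_id": s.patient_id, "day": int(d), "ybocs_total": v}
        for s in series_list
        for d, v in zip(s.days, s.scores)
    ]
    pd.DataFrame(rows, columns=["patient_id", "day", "ybocs_total"]).to_csv(path, index=False)


def load_events(path: str | Path) -> list[EventMetadata]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for _, row in df.iterrows():
        onset = row["erp_onset_day"]
        out.append(
            EventMetadata(
                patient_id=row["patient_id"],
                treatment_start_day=int(row["treatment_start_day"]),
                treatment_end_day=int(row["treatment_end_day"]),
                erp_onset_day=None if pd.isna(onset) else int(onset),
            )
        )
    return out


def write_events(events: list[EventMetadata], path: str | Path) -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "erp_onset_day": "" if e.erp_onset_day is None else e.erp_onset_day,
            "treatment_start_day": e.treatment_start_day,
            "treatment_end_day": e.treatment_end_day,
        }
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "erp_onset_day", "treatment_start_day", "treatment_end_day"]
    ).to_csv(path, index=False)


def load_factor_config(path: str | Path) -> tuple[FactorMap, dict[str, RatingScale]]:
    """Read the factor map plus per-item scale bounds from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    fmap = FactorMap(
        factors={str(k): [str(i) for i in v] for k, v in cfg["factors"].items()},
        motivation_item=str(cfg["motivation_item"]),
        symptom_factor=str(cfg["symptom_factor"]),
        boundary_factors=[str(f) for f in cfg.get("boundary_factors", [])],
    )
    scales = {
        str(item): RatingScale(float(lo), float(hi))
        for item, (lo, hi) in cfg["scales"].items()
    }
    return fmap, scales


def write_factor_config(
    fmap: FactorMap, scales: dict[str, RatingScale], path: str | Path
) -> None:
    cfg = {
        "factors": {k: list(v) for k, v in fmap.factors.items()},
        "motivation_item": fmap.motivation_item,
        "symptom_factor": fmap.symptom_factor,
        "boundary_factors": list(fmap.boundary_factors),
        "scales": {item: [s.min_value, s.max_value] for item, s in scales.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Series operations
# ---------------------------------------------------------------------------

def impute_short_gaps(series: RatingSeries, max_gap: int = 2) -> RatingSeries:
    """Linearly interpolate runs of at most ``max_gap`` consecutive missing days.

    Longer runs and leading/trailing missing stretches are left untouched;
    observed values are never altered, so the operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    values = series.values.copy()
    isnan = np.isnan(values)
    if not isnan.any() or max_gap == 0:
        return replace(series, values=values)
    n = values.size
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        # gap runs from i to j-1; flanked only if both sides observed
        if i > 0 and j < n and (j - i) <= max_gap:
            left_day, right_day = series.days[i - 1], series.days[j]
            left_val, right_val = values[i - 1], values[j]
            for k in range(i, j):
                frac = (series.days[k] - left_day) / (right_day - left_day)
                values[k] = left_val + frac * (right_val - left_val)
        i = j
    return replace(series, values=values)


def factor_score_series(
    series_set: list[RatingSeries], factor_id: str, fmap: FactorMap
) -> RatingSeries:
    """Per-day available-case mean of a factor's item series for one patient."""
    items = fmap.factors.get(factor_id)
    if not items:
        raise ValueError(f"unknown factor {factor_id!r}")
    members = [s for s in series_set if s.item_id in items]
    if not members:
        raise ValueError(f"no item series present for factor {factor_id!r}")
    scales = {(s.scale.min_value, s.scale.max_value) for s in members}
    if len(scales) > 1:
        raise ValueError(f"factor {factor_id!r} items are on heterogeneous scales: {scales}")
    pids = {s.patient_id for s in members}
    if len(pids) > 1:
        raise ValueError(f"factor scoring mixes patients {pids}")

    all_days = np.unique(np.concatenate([s.days for s in members]))
    stacked = np.full((len(members), all_days.size), np.nan)
    for row, s in enumerate(members):
        idx = np.searchsorted(all_days, s.days)
        stacked[row, idx] = s.values
    counts = (~np.isnan(stacked)).sum(axis=0)
    sums = np.nansum(np.where(np.isnan(stacked), 0.0, stacked), axis=0)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RatingSeries(
        patient_id=members[0].patient_id,
        item_id=f"factor:{factor_id}",
        days=all_days,
        values=means,
        scale=members[0].scale,
    )


def patient_mean_level(
    series: RatingSeries, day_range: tuple[int, int] | None = None
) -> float:
    """Mean of non-missing values within an inclusive day range (whole series if None)."""
    mask = np.ones(len(series), dtype=bool)
    if day_range is not None:
        lo, hi = day_range
        mask = (series.days >= lo) & (series.days <= hi)
    vals = series.values[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(
            f"no observed values in day range {day_range} "
            f"(patient {series.patient_id}, item {series.item_id})"
        )
    return float(vals.mean())
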