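"""Synthetic cohorts of daily process ratings, biweekly outcomes, and events.

The generator emulates the statistical structure the analysis chain assumes,
so every pipeline stage can be exercised and scored against a known ground
truth:

* a latent symptom state per patient that is a step function — constant at a
  pre level, dropping by delta at an order-transition day tau (sudden gain);
* a critical-instability burst in the days just before tau, during which item
  noise is inflated (gain kappa) and values excursion toward the scale
  extremes, elevating both the fluctuation and the distribution measure;
* optionally a second, milder instability window at the start of treatment
  (the "initial instability" seen at the group level);
* stable interpersonal-climate factors (ward atmosphere, therapist
  relationship) around patient-specific levels;
* Y-BOCS outcomes assessed twice per week as a noisy affine readout of the
  latent state, and exposure (ERP) onset lagging the transition by a few days
  for the participating subset.

The improvement delta is coupled to the instability gain and to the
atmosphere level (and their product), so the headline correlational and
factorial signatures have a programmed ground truth.  All randomness flows
from the config seed; identical configs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core_data import (
    EventMetadata,
    FactorMap,
    OutcomeSeries,
    RatingScale,
    RatingSeries,
)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "CohortBundle",
    "default_factor_map",
    "simulate_patient",
    "simulate_cohort",
    "score_detection",
]


def default_factor_map() -> FactorMap:
    """Five factors totalling 47 items, mirroring a TPQ-like instrument."""
    factors = {
        "progress": [f"prog_{i:02d}" for i in range(1, 13)],          # incl. motivation
        "symptoms": [f"symp_{i:02d}" for i in range(1, 11)],
        "therapist_rel": [f"ther_{i:02d}" for i in range(1, 10)],
        "dysphoric": [f"dysp_{i:02d}" for i in range(1, 10)],
        "ward_atmosphere": [f"ward_{i:02d}" for i in range(1, 8)],
    }
    return FactorMap(
        factors=factors,
        motivation_item="prog_01",
        symptom_factor="symptoms",
        boundary_factors=["ward_atmosphere", "therapist_rel"],
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults mirror the emulated study conditions.

    Sample-level marginals (cohort size 23, treatment duration 60.2 +/- 12.7
    days, Y-BOCS pre 21.8 +/- 8.5, symptom-factor pre level around 4.5 on a
    0-6 scale, 18 of 23 ERP participants) follow the emulated cohort; the
    generative mechanics (AR(1) item noise, burst gain, couplings) are this
    package's own modelling choices.
    """

    n_patients: int = 23
    mean_duration_days: float = 60.2
    sd_duration_days: float = 12.7
    min_duration_days: int = 20
    scale_min: float = 0.0
    scale_max: float = 6.0
    ar_coefficient: float = 0.5
    noise_sd: float = 0.8
    # order transition & burst
    transition_frac_range: tuple[float, float] = (0.45, 0.65)
    burst_length_range: tuple[int, int] = (7, 11)
    burst_gain_mean: float = 2.5
    burst_gain_sd: float = 0.6
    burst_gain_min: float = 1.2
    p_flip: float = 0.3
    initial_instability: bool = True
    initial_length: int = 6
    initial_gain: float = 1.8
    initial_p_flip: float = 0.15
    # symptom state and couplings (negative change = improvement)
    symptom_pre_mean: float = 4.5
    symptom_pre_sd: float = 1.0
    delta_base: float = 1.545
    beta_c: float = -0.35
    beta_w: float = -0.25
    beta_int: float = -0.04
    delta_noise_sd: float = 0.3
    # interpersonal climate
    atmosphere_mean: float = 4.2
    atmosphere_sd: float = 0.6
    motivation_mean: float = 3.8
    motivation_sd: float = 0.6
    # outcomes
    ybocs_pre_mean: float = 21.8
    ybocs_pre_sd: float = 8.5
    ybocs_gain: float = 8.9          # Y-BOCS points per unit of latent symptom state
    ybocs_noise_sd: float = 1.5
    erp_lag_range: tuple[int, int] = (4, 7)
    erp_participation: float = 18 / 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_duration_days < 0 or self.noise_sd < 0 or self.delta_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.erp_participation <= 1.0):
            raise ValueError("erp_participation must be a probability")
        if not (0.0 <= self.p_flip <= 1.0 and 0.0 <= self.initial_p_flip <= 1.0):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.min_duration_days < 20:
            raise ValueError("durations below 20 points violate the validity floor")
        if self.burst_length_range[0] < 1 or self.burst_length_range[1] < self.burst_length_range[0]:
            raise ValueError("invalid burst_length_range")

    @property
    def scale(self) -> RatingScale:
        return RatingScale(self.scale_min, self.scale_max)


@dataclass
class SyntheticTruth:
    patient_id: str
    duration: int
    tau: int                      # first day of the post-transition regime
    burst_start: int
    burst_end: int                # inclusive; burst occupies [burst_start, burst_end]
    kappa: float
    atmosphere: float
    delta: float                  # realized latent improvement (negative = better)
    erp_onset: int | None
    symptom_pre: float


@dataclass
class CohortBundle:
    ratings: list[RatingSeries]
    outcomes: list[OutcomeSeries]
    events: list[EventMetadata]
    truths: list[SyntheticTruth]
    factor_map: FactorMap
    scales: dict[str, RatingScale]
    config: CohortConfig

    def patient_ratings(self, patient_id: str) -> list[RatingSeries]:
        return [s for s in self.ratings if s.patient_id == patient_id]


def _ar1(rng: np.random.Generator, n_items: int, n_days: int, phi: float, sd: float) -> np.ndarray:
    """AR(1) noise with stationary sd ``sd``, shape (n_items, n_days)."""
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    eps = rng.normal(0.0, innov_sd, size=(n_items, n_days))
    out = np.empty_like(eps)
    out[:, 0] = rng.normal(0.0, sd, size=n_items)
    for t in range(1, n_days):
        out[:, t] = phi * out[:, t - 1] + eps[:, t]
    return out


def _round_clip(values: np.ndarray, scale: RatingScale) -> np.ndarray:
    # round first (ordinal items), clip last so bounds are guaranteed
    return np.clip(np.round(values), scale.min_value, scale.max_value)


def simulate_patient(
    config: CohortConfig,
    patient_id: str,
    rng: np.random.Generator,
    erp: bool = True,
) -> tuple[list[RatingSeries], OutcomeSeries, EventMetadata, SyntheticTruth]:
    """Generate one patient's ratings, outcomes, events, and ground truth."""
    fmap = default_factor_map()
    scale = config.scale

    # --- treatment duration ---------------------------------------------
    duration = int(np.round(rng.normal(config.mean_duration_days, config.sd_duration_days)))
    duration = max(duration, config.min_duration_days)
    days = np.arange(duration)

    # --- transition placement -------------------------------------------
    lo, hi = config.transition_frac_range
    tau = int(np.round(rng.uniform(lo, hi) * (duration - 1)))
    burst_len = int(rng.integers(config.burst_length_range[0], config.burst_length_range[1] + 1))
    erp_lag = int(rng.integers(config.erp_lag_range[0], config.erp_lag_range[1] + 1))
    tau = min(tau, duration - erp_lag - 2)
    init_end = config.initial_length - 1 if config.initial_instability else -1
    # keep the burst inside the pre-transition span, clear of the initial window
    max_len = tau - (init_end + 2)
    if max_len < 1:
        raise ValueError(
            f"infeasible config: no room for a burst before the transition "
            f"(duration {duration}, tau {tau})"
        )
    burst_len = min(burst_len, max_len)
    burst_start, burst_end = tau - burst_len, tau - 1

    # --- patient-level parameters ---------------------------------------
    atmosphere = float(np.clip(rng.normal(config.atmosphere_mean, config.atmosphere_sd), 2.0, 5.8))
    ther_rel = float(
        np.clip(config.atmosphere_mean + 0.6 * (atmosphere - config.atmosphere_mean)
                + rng.normal(0.0, 0.35), 2.0, 5.8)
    )
    motivation = float(
        np.clip(config.motivation_mean + 0.4 * (ther_rel - config.atmosphere_mean)
                + rng.normal(0.0, config.motivation_sd), 1.0, 5.8)
    )
    kappa = float(
        max(rng.normal(config.burst_gain_mean, config.burst_gain_sd), config.burst_gain_min)
    )
    s_pre = float(np.clip(rng.normal(config.symptom_pre_mean, config.symptom_pre_sd), 2.0, 5.8))
    delta = (
        config.delta_base
        + config.beta_c * kappa
        + config.beta_w * atmosphere
        + config.beta_int * kappa * atmosphere
        + rng.normal(0.0, config.delta_noise_sd)
    )
    s_post = float(np.clip(s_pre + delta, 0.2, scale.max_value - 0.2))
    delta = s_post - s_pre
    s = np.where(days < tau, s_pre, s_post)

    # --- per-item mean trajectories --------------------------------------
    item_ids = fmap.item_ids
    n_items = len(item_ids)
    levels = np.empty((n_items, duration))
    burst_items = np.zeros(n_items, dtype=bool)
    for row, item in enumerate(item_ids):
        factor = fmap.factor_of(item)
        offset = rng.normal(0.0, 0.3)
        if factor == "symptoms":
            levels[row] = s + offset
            burst_items[row] = True
        elif factor == "progress":
            if item == fmap.motivation_item:
                levels[row] = motivation
            else:
                levels[row] = 3.0 + offset + 0.6 * (days >= tau)
            burst_items[row] = True
        elif factor == "dysphoric":
            levels[row] = 3.0 + offset - 0.6 * (days >= tau)
            burst_items[row] = True
        elif factor == "therapist_rel":
            levels[row] = ther_rel + offset * 0.5
        else:  # ward_atmosphere
            levels[row] = atmosphere + offset * 0.5
    # climate factors fluctuate less than the state-coupled items
    noise_sd = np.where(burst_items, config.noise_sd, 0.5 * config.noise_sd)

    noise = _ar1(rng, n_items, duration, config.ar_coefficient, 1.0) * noise_sd[:, None]

    # --- instability windows: variance inflation + extreme excursions ----
    def apply_window(start: int, end: int, gain: float, p_flip: float) -> None:
        win = (days >= start) & (days <= end)
        noise[np.ix_(burst_items, np.nonzero(win)[0])] *= gain
        win_days = np.nonzero(win)[0]
        for row in np.nonzero(burst_items)[0]:
            phase = int(rng.integers(0, 2))
            flips = rng.random(win_days.size) < p_flip
            for k, t in enumerate(win_days):
                if flips[k]:
                    extreme = scale.max_value if (k + phase) % 2 == 0 else scale.min_value
                    levels[row, t] = extreme
                    noise[row, t] = 0.0

    if burst_len >= 1:
        # excursion rate scales with the burst intensity so that kappa is the
        # single dial of the critical-instability mechanics (kappa=1 -> none)
        p_eff = min(
            1.0,
            config.p_flip * max(kappa - 1.0, 0.0) / max(config.burst_gain_mean - 1.0, 1e-9),
        )
        apply_window(burst_start, burst_end, kappa, p_eff)
    if config.initial_instability:
        apply_window(0, init_end, config.initial_gain, config.initial_p_flip)

    values = _round_clip(levels + noise, scale)
    ratings = [
        RatingSeries(patient_id, item, days.copy(), values[row].astype(float), scale)
        for row, item in enumerate(item_ids)
    ]

    # --- biweekly outcome readout ----------------------------------------
    ybocs_pre = float(np.clip(rng.normal(config.ybocs_pre_mean, config.ybocs_pre_sd), 8.0, 38.0))
    outcome_days = days[(days % 7 == 0) | (days % 7 == 3)]
    y = ybocs_pre + config.ybocs_gain * (s[outcome_days] - s_pre)
    y = y + rng.normal(0.0, config.ybocs_noise_sd, size=outcome_days.size)
    y = np.clip(np.round(y), 0.0, 40.0)
    outcomes = OutcomeSeries(patient_id, outcome_days, y)

    erp_onset = int(tau + erp_lag) if erp else None
    event = EventMetadata(
        patient_id=patient_id,
        treatment_start_day=0,
        treatment_end_day=int(duration - 1),
        erp_onset_day=erp_onset,
    )
    truth = SyntheticTruth(
        patient_id=patient_id,
        duration=duration,
        tau=int(tau),
        burst_start=int(burst_start),
        burst_end=int(burst_end),
        kappa=kappa,
        atmosphere=atmosphere,
        delta=float(delta),
        erp_onset=erp_onset,
        symptom_pre=s_pre,
    )
    return ratings, outcomes, event, truth


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Independent patients from per-patient streams derived from the master seed.

    The number of ERP participants is the rounded participation fraction of
    the cohort; which patients participate is drawn from the master stream.
    """
    master = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    n = config.n_patients
    n_erp = int(np.round(config.erp_participation * n))
    erp_idx = set(cohort_rng.choice(n, size=n_erp, replace=False).tolist())

    ratings: list[RatingSeries] = []
    outcomes: list[OutcomeSeries] = []
    events: list[EventMetadata] = []
    truths: list[SyntheticTruth] = []
    child_seeds = master.spawn(n + 1)[1:]
    for i in range(n):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(child_seeds[i])
        r, o, e, t = simulate_patient(config, pid, rng, erp=(i in erp_idx))
        ratings.extend(r)
        outcomes.append(o)
        events.append(e)
        truths.append(t)
    fmap = default_factor_map()
    scales = {item: config.scale for item in fmap.item_ids}
    return CohortBundle(ratings, outcomes, events, truths, fmap, scales, config)


def score_detection(
    truths: list[SyntheticTruth],
    profiles: dict[str, "object"],
    gradient_reports: list | None = None,
    window_width: int = 7,
    argmax_days: dict[str, int] | None = None,
) -> dict[str, float]:
    """Recovery metrics against the generator's ground truth.

    * ``phase_hit_rate``: fraction of patients for whom a detected phase
      (anchor interval, windows extending window_width-1 days beyond the end)
      overlaps the true burst window.
    * ``median_localization_error``: |midpoint of the argmax-complexity window
      - midpoint of the true burst| (days), median over patients; requires
      ``argmax_days`` mapping patient -> argmax anchor day.
    * ``pre_erp_gradient_fraction``: fraction of ERP patients whose steepest
      outcome drop is completed by relative day 0.
    """
    by_pid = {t.patient_id: t for t in truths}
    hits, loc_errors = [], []
    for pid, profile in profiles.items():
        truth = by_pid[pid]
        hit = False
        for start, end in profile.phases:
            covered = (start, end + window_width - 1)
            if covered[0] <= truth.burst_end and covered[1] >= truth.burst_start:
                hit = True
                break
        hits.append(hit)
        if argmax_days is not None and pid in argmax_days:
            anchor = argmax_days[pid]
            win_mid = anchor + (window_width - 1) / 2.0
            burst_mid = (truth.burst_start + truth.burst_end) / 2.0
            loc_errors.append(abs(win_mid - burst_mid))
    metrics: dict[str, float] = {}
    if hits:
        metrics["phase_hit_rate"] = float(np.mean(hits))
    if loc_errors:
        metrics["median_localization_error"] = float(np.median(loc_errors))
    if gradient_reports:
        pre = [
            r.location_vs_event <= 0
            for r in gradient_reports
            if r.location_vs_event is not None
        ]
        if pre:
            metrics["pre_erp_gradient_fraction"] = float(np.mean(pre))
    return metrics


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
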