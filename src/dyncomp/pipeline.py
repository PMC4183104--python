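"""End-to-end orchestration: from raw tables to the cohort table and tests.

This module glues the stages together in the order the analysis chain runs:
complexity matrices -> instability profiles and scores -> patient-level
cohort table -> correlations, median-split 2x2 ANOVA with post-hoc tests,
and block-wise hierarchical regression -> ERP-aligned transition analysis.
The CLI and the numbered analysis scripts are thin wrappers around these
functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import instability as ins
from . import stats as st
from .complexity import ComplexityMatrix, ComplexityParams, complexity_matrix, mean_complexity_curve
from .core_data import (
    EventMetadata,
    FactorMap,
    OutcomeSeries,
    RatingSeries,
    factor_score_series,
    impute_short_gaps,
    patient_mean_level,
)

__all__ = [
    "complexity_matrices",
    "build_profiles",
    "build_cohort_table",
    "run_statistics",
    "run_erp_alignment",
    "table3_frame",
    "analyze_cohort",
]

logger = logging.getLogger(__name__)


def _group_by_patient(ratings: list[RatingSeries]) -> dict[str, list[RatingSeries]]:
    out: dict[str, list[RatingSeries]] = {}
    for s in ratings:
        out.setdefault(s.patient_id, []).append(s)
    return out


def complexity_matrices(
    ratings: list[RatingSeries],
    params: ComplexityParams = ComplexityParams(),
    impute_max_gap: int = 2,
    item_order: list[str] | None = None,
) -> dict[str, ComplexityMatrix]:
    """Per-patient complexity resonance matrices (short gaps imputed first)."""
    matrices: dict[str, ComplexityMatrix] = {}
    for pid, series_set in _group_by_patient(ratings).items():
        imputed = [impute_short_gaps(s, impute_max_gap) for s in series_set]
        if len(imputed[0]) < params.min_series_length:
            logger.warning(
                "patient %s excluded: %d days < validity floor %d",
                pid, len(imputed[0]), params.min_series_length,
            )
            continue
        matrices[pid] = complexity_matrix(imputed, params, item_order)
    return matrices


def build_profiles(
    matrices: dict[str, ComplexityMatrix],
    alpha: float = 0.05,
    phase_source: str = "frequency",
) -> dict[str, ins.InstabilityProfile]:
    return {pid: ins.build_profile(m, alpha, phase_source) for pid, m in matrices.items()}


def build_cohort_table(
    ratings: list[RatingSeries],
    outcomes: list[OutcomeSeries],
    events: list[EventMetadata],
    fmap: FactorMap,
    params: ComplexityParams = ComplexityParams(),
    score_variant: str = "per_item",
    impute_max_gap: int = 2,
) -> pd.DataFrame:
    """One row per patient with the levels, scores, and relative changes.

    Columns: ward_atmosphere and therapist_rel (mean boundary-factor levels),
    motivation (mean of the designated item), erp_motivation (mean within the
    ERP phase, NaN for non-participants), instability (max-minus-mean
    complexity score), rel_ybocs_change and rel_tpq_change (percent, negative
    = improvement).  Patients failing a stage are dropped from that column
    with a logged reason (listwise handling happens per analysis downstream).
    """
    matrices = complexity_matrices(ratings, params, impute_max_gap)
    outcome_by_pid = {o.patient_id: o for o in outcomes}
    event_by_pid = {e.patient_id: e for e in events}
    ward_f, ther_f = (fmap.boundary_factors + [None, None])[:2]

    rows = []
    for pid, series_set in _group_by_patient(ratings).items():
        row: dict[str, float | str] = {"patient_id": pid}
        imputed = [impute_short_gaps(s, impute_max_gap) for s in series_set]
        try:
            if ward_f:
                row["ward_atmosphere"] = patient_mean_level(
                    factor_score_series(imputed, ward_f, fmap)
                )
            if ther_f:
                row["therapist_rel"] = patient_mean_level(
                    factor_score_series(imputed, ther_f, fmap)
                )
            motiv = next(s for s in imputed if s.item_id == fmap.motivation_item)
            row["motivation"] = patient_mean_level(motiv)
            event = event_by_pid.get(pid)
            if event is not None and event.erp_onset_day is not None:
                row["erp_motivation"] = patient_mean_level(
                    motiv, (event.erp_onset_day, event.treatment_end_day)
                )
            if pid in matrices:
                row["instability"] = ins.max_mean_score(matrices[pid], score_variant).score
            sym = factor_score_series(imputed, fmap.symptom_factor, fmap)
            pre, post = st.weekly_symptom_means(sym)
            row["tpq_sym_pre"], row["tpq_sym_post"] = pre, post
            row["rel_tpq_change"] = st.relative_change(pre, post)
            out = outcome_by_pid.get(pid)
            if out is not None and len(out) >= 2:
                row["ybocs_pre"] = float(out.scores[0])
                row["ybocs_post"] = float(out.scores[-1])
                row["rel_ybocs_change"] = st.relative_change(
                    float(out.scores[0]), float(out.scores[-1])
                )
        except (ValueError, StopIteration) as exc:
            logger.warning("patient %s partially excluded: %s", pid, exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def run_statistics(table: pd.DataFrame) -> dict:
    """Correlations, median-split 2x2 ANOVA + post-hoc, hierarchical regression.

    Returns a JSON-serializable dict; each analysis uses listwise-complete
    rows and records its n.
    """
    results: dict = {"correlations": {}, "anova": {}, "regression": {}}

    pairs = [
        ("ward_atmosphere", "rel_ybocs_change"),
        ("ward_atmosphere", "rel_tpq_change"),
        ("therapist_rel", "rel_ybocs_change"),
        ("therapist_rel", "rel_tpq_change"),
        ("instability", "rel_ybocs_change"),
        ("instability", "rel_tpq_change"),
        ("motivation", "rel_ybocs_change"),
        ("motivation", "rel_tpq_change"),
        ("erp_motivation", "rel_tpq_change"),
        ("erp_motivation", "rel_ybocs_change"),
        ("motivation", "therapist_rel"),
        ("ward_atmosphere", "therapist_rel"),
        ("rel_ybocs_change", "rel_tpq_change"),
    ]
    for x, y in pairs:
        if x not in table.columns or y not in table.columns:
            continue
        sub = table[[x, y]].dropna()
        try:
            res = st.correlate(sub[x].to_numpy(), sub[y].to_numpy())
        except ValueError as exc:
            logger.warning("correlation %s ~ %s skipped: %s", x, y, exc)
            continue
        results["correlations"][f"{x}~{y}"] = asdict(res)

    needed = {"instability", "ward_atmosphere"}
    if needed.issubset(table.columns):
        base = table.dropna(subset=["instability", "ward_atmosphere"])
        comp_split = st.median_split(base["instability"].to_numpy())
        ward_split = st.median_split(base["ward_atmosphere"].to_numpy())
        results["median_splits"] = {
            "instability": {"median": comp_split.median,
                            "n_low": comp_split.n_low, "n_high": comp_split.n_high},
            "ward_atmosphere": {"median": ward_split.median,
                                "n_low": ward_split.n_low, "n_high": ward_split.n_high},
        }
        for outcome in ("rel_ybocs_change", "rel_tpq_change"):
            if outcome not in base.columns:
                continue
            sub = base.dropna(subset=[outcome])
            comp_lab = comp_split.labels[base.index.get_indexer(sub.index)]
            ward_lab = ward_split.labels[base.index.get_indexer(sub.index)]
            y = sub[outcome].to_numpy()
            try:
                effects = st.anova_2x2(y, comp_lab, ward_lab)
            except ValueError as exc:
                logger.warning("ANOVA on %s skipped: %s", outcome, exc)
                continue
            cell_means = {
                f"{c}_complexity/{w}_atmosphere": float(
                    y[(comp_lab == c) & (ward_lab == w)].mean()
                )
                for c in ("low", "high")
                for w in ("low", "high")
                if np.any((comp_lab == c) & (ward_lab == w))
            }
            entry = {
                "n": int(y.size),
                "effects": {k: asdict(v) for k, v in effects.items()},
                "cell_means": cell_means,
            }
            good = ward_lab == "high"
            hi, lo = y[good & (comp_lab == "high")], y[good & (comp_lab == "low")]
            if hi.size >= 2 and lo.size >= 2:
                try:
                    entry["posthoc_good_atmosphere_high_vs_low_complexity"] = asdict(
                        st.posthoc_t(hi, lo)
                    )
                except ValueError as exc:
                    logger.warning("post-hoc on %s skipped: %s", outcome, exc)
            results["anova"][outcome] = entry

    block_spec = [
        ("motivation", ["motivation"]),
        ("ward_atmosphere", ["ward_atmosphere"]),
        ("complexity", ["instability"]),
    ]
    predictors = [p for _, preds in block_spec for p in preds]
    for outcome in ("rel_ybocs_change", "rel_tpq_change"):
        cols = [c for c in predictors + [outcome] if c in table.columns]
        if outcome not in cols:
            continue
        sub = table[cols].dropna()
        blocks = [
            (name, {p: sub[p].to_numpy() for p in preds})
            for name, preds in block_spec
            if all(p in sub.columns for p in preds)
        ]
        try:
            res = st.hierarchical_regression(sub[outcome].to_numpy(), blocks)
        except ValueError as exc:
            logger.warning("regression on %s skipped: %s", outcome, exc)
            continue
        results["regression"][outcome] = [asdict(b) for b in res]
    return results


def table3_frame(blocks: list[dict]) -> pd.DataFrame:
    """Human-readable block-wise regression table (one row per predictor)."""
    rows = []
    for b in blocks:
        first = True
        for pred in b["predictors"]:
            rows.append(
                {
                    "Model": b["block"] if first else "",
                    "Included variables": pred,
                    "beta": round(b["beta"][pred], 3),
                    "T": round(b["t"][pred], 3),
                    "P": round(b["p"][pred], 3),
                    "R2": round(b["r_squared"], 3) if first else "",
                    "R2 change": round(b["r_squared_change"], 3) if first else "",
                    "F change": round(b["f_change"], 2) if first else "",
                    "P change": round(b["p_change"], 3) if first else "",
                }
            )
            first = False
    return pd.DataFrame(rows)


def run_erp_alignment(
    outcomes: list[OutcomeSeries],
    events: list[EventMetadata],
    matrices: dict[str, ComplexityMatrix] | None = None,
    pre_erp_window: tuple[int, int] = (-11, -4),
) -> dict:
    """ERP-aligned analysis of outcome and complexity trajectories.

    Z-transforms each ERP participant's outcome series, aligns it to onset,
    averages on the half-weekly grid, and locates the steepest gradient of
    the group mean curve and of each individual.  If complexity matrices are
    supplied, each patient's mean complexity curve is aligned too and the
    elevation of the pre-onset candidate window is tested against the mean
    complexity outside it (paired t over patients).
    """
    aligned, excluded = al.align_cohort(outcomes, events, z=True)
    out: dict = {"n_aligned": len(aligned), "excluded": excluded}
    if len(aligned) < 2:
        return out

    curve = al.group_mean_curve(aligned)
    out["group_curve"] = curve
    grads = [al.steepest_gradient(s) for s in aligned]
    out["gradients"] = grads
    out["pre_erp_gradient_fraction"] = float(
        np.mean([g.location_vs_event <= 0 for g in grads])
    )
    curve_series = al.AlignedSeries(
        "group", curve["relative_day"].to_numpy().astype(int), curve["mean"].to_numpy()
    )
    out["group_steepest"] = al.steepest_gradient(curve_series)

    # symptom level at onset vs level before each patient's steepest drop
    at_onset, before = [], []
    for s, g in zip(aligned, grads):
        dist = np.abs(s.relative_days - 0)
        k = int(np.argmin(dist))
        if dist[k] > 2:
            continue
        pre_mask = s.relative_days < g.steepest_interval[0]
        if not pre_mask.any():
            continue
        at_onset.append(s.values[k])
        before.append(float(s.values[pre_mask].mean()))
    if len(at_onset) >= 2:
        try:
            out["onset_level_test"] = al.phase_elevation_test(
                np.array(at_onset), np.array(before)
            )
        except ValueError as exc:
            logger.warning("onset-level test skipped: %s", exc)

    if matrices:
        event_by_pid = {e.patient_id: e for e in events}
        in_win, outside = [], []
        for pid, matrix in matrices.items():
            event = event_by_pid.get(pid)
            if event is None or event.erp_onset_day is None:
                continue
            days, mc = mean_complexity_curve(matrix)
            rel = days - event.erp_onset_day
            lo, hi = pre_erp_window
            win = (rel >= lo) & (rel <= hi) & ~np.isnan(mc)
            rest = ~((rel >= lo) & (rel <= hi)) & ~np.isnan(mc)
            if win.any() and rest.any():
                in_win.append(float(mc[win].mean()))
                outside.append(float(mc[rest].mean()))
        if len(in_win) >= 2:
            try:
                out["pre_erp_complexity_test"] = al.phase_elevation_test(
                    np.array(in_win), np.array(outside)
                )
            except ValueError as exc:
                logger.warning("pre-ERP complexity test skipped: %s", exc)
    return out


def analyze_cohort(
    ratings: list[RatingSeries],
    outcomes: list[OutcomeSeries],
    events: list[EventMetadata],
    fmap: FactorMap,
    params: ComplexityParams = ComplexityParams(),
    alpha: float = 0.05,
    score_variant: str = "per_item",
    out_dir: str | Path | None = None,
    erp_alignment: bool = True,
) -> dict:
    """Run the full chain and optionally write every intermediate artifact."""
    matrices = complexity_matrices(ratings, params, item_order=fmap.item_ids)
    profiles = build_profiles(matrices, alpha)
    table = build_cohort_table(ratings, outcomes, events, fmap, params, score_variant)
    statistics = run_statistics(table)
    results: dict = {
        "matrices": matrices,
        "profiles": profiles,
        "cohort_table": table,
        "statistics": statistics,
    }
    if erp_alignment:
        results["erp"] = run_erp_alignment(outcomes, events, matrices)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for pid, m in matrices.items():
            m.to_frame().to_csv(out_dir / f"complexity_{pid}.csv")
        manifest.append("complexity matrices")
        phase_rows = [
            {"patient_id": pid, "start_day": a, "end_day": b}
            for pid, prof in profiles.items()
            for a, b in prof.phases
        ]
        pd.DataFrame(phase_rows, columns=["patient_id", "start_day", "end_day"]).to_csv(
            out_dir / "phases.csv", index=False
        )
        freq_rows = [
            {"patient_id": pid, "day": int(d), "percent": f}
            for pid, prof in profiles.items()
            for d, f in zip(prof.days, prof.frequency)
        ]
        pd.DataFrame(freq_rows).to_csv(out_dir / "instability_frequency.csv", index=False)
        manifest.append("instability profiles")
        table.to_csv(out_dir / "cohort_table.csv")
        manifest.append("cohort table")
        with open(out_dir / "statistics.json", "w") as fh:
            json.dump(statistics, fh, indent=2, default=_jsonify)
        for outcome, blocks in statistics.get("regression", {}).items():
            table3_frame(blocks).to_csv(out_dir / f"regression_{outcome}.csv", index=False)
        manifest.append("statistics")
        if erp_alignment and "erp" in results and "group_curve" in results["erp"]:
            results["erp"]["group_curve"].to_csv(out_dir / "erp_group_curve.csv", index=False)
            erp_json = {
                k: _jsonify(v)
                for k, v in results["erp"].items()
                if k not in ("group_curve", "gradients")
            }
            erp_json["gradients"] = [_jsonify(g) for g in results["erp"].get("gradients", [])]
            with open(out_dir / "erp_report.json", "w") as fh:
                json.dump(erp_json, fh, indent=2, default=_jsonify)
            manifest.append("ERP alignment")
        (out_dir / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return results


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    return obj
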