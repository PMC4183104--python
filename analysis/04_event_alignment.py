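"""Order transitions relative to the major intervention (ERP onset = day 0).

Z-transforms each ERP participant's Y-BOCS trajectory, aligns it so exposure
onset is relative day 0, averages trajectories on a half-weekly grid, and
asks the key directional question: does the steepest symptom drop fall
*before* the intervention?  Also tests whether mean dynamic complexity is
elevated in the pre-onset candidate window (11-4 days before ERP).
"""

import pathlib

from dyncomp import pipeline
from dyncomp.core_data import load_events, load_factor_config, load_outcomes, load_ratings

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "erp"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fmap, scales = load_factor_config(ROOT / "cohort" / "factors.yaml")
    ratings = load_ratings(ROOT / "cohort" / "ratings.csv", scales)
    outcomes = load_outcomes(ROOT / "cohort" / "outcomes.csv")
    events = load_events(ROOT / "cohort" / "events.csv")

    matrices = pipeline.complexity_matrices(ratings, item_order=fmap.item_ids)
    rep = pipeline.run_erp_alignment(outcomes, events, matrices)

    rep["group_curve"].to_csv(OUT / "group_curve.csv", index=False)
    print(f"aligned {rep['n_aligned']} ERP participants "
          f"({len(rep['excluded'])} excluded: no onset) -> {OUT}")

    n_pre = round(rep["pre_erp_gradient_fraction"] * rep["n_aligned"])
    print(f"  steepest individual symptom drop at or before onset: "
          f"{n_pre} of {rep['n_aligned']} patients "
          f"({100 * rep['pre_erp_gradient_fraction']:.0f}%)")
    g = rep["group_steepest"]
    print(f"  group mean z-curve steepest gradient: {g.gradient:.2f} z-units over "
          f"relative days {g.steepest_interval}")
    if "onset_level_test" in rep:
        t = rep["onset_level_test"]
        print(f"  symptom level at onset vs pre-drop level: "
              f"t({t.df}) = {t.t:.2f}, p = {t.p:.3g}, d_z = {t.d_z:.2f}")
    if "pre_erp_complexity_test" in rep:
        t = rep["pre_erp_complexity_test"]
        print(f"  mean complexity in the 11-4 days pre-onset window vs outside: "
              f"t({t.df}) = {t.t:.2f}, p = {t.p:.3g}, d_z = {t.d_z:.2f}")


if __name__ == "__main__":
    main()
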