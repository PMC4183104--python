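"""Dynamic complexity of every item trajectory: the complexity resonance maps.

Computes F, D and C = F*D in a 7-day moving window for each of the 47 items
of each patient, writes the items x days complexity matrices to
results/complexity/, and renders one representative patient's complexity
resonance diagram with the detected instability phases and the ERP onset
overlaid.
"""

import pathlib

import numpy as np

from dyncomp import pipeline
from dyncomp.core_data import load_events, load_factor_config, load_ratings
from dyncomp.plotting import render_resonance_diagram

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "complexity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fmap, scales = load_factor_config(ROOT / "cohort" / "factors.yaml")
    ratings = load_ratings(ROOT / "cohort" / "ratings.csv", scales)
    events = {e.patient_id: e for e in load_events(ROOT / "cohort" / "events.csv")}

    matrices = pipeline.complexity_matrices(ratings, item_order=fmap.item_ids)
    profiles = pipeline.build_profiles(matrices)
    for pid, matrix in matrices.items():
        matrix.to_frame().to_csv(OUT / f"complexity_{pid}.csv")

    c_all = np.concatenate([m.C[~np.isnan(m.C)] for m in matrices.values()])
    print(f"complexity matrices for {len(matrices)} patients -> {OUT}")
    print(f"  C over all items/days: mean {c_all.mean():.3f}, "
          f"95th percentile {np.percentile(c_all, 95):.3f}, max {c_all.max():.3f}")

    pid = sorted(m for m in matrices if events[m].erp_onset_day is not None)[0]
    render_resonance_diagram(
        matrices[pid], OUT / f"resonance_{pid}.png",
        phases=profiles[pid].phases, erp_onset=events[pid].erp_onset_day,
    )
    print(f"  resonance diagram for {pid}: {len(profiles[pid].phases)} detected "
          f"phase(s) {profiles[pid].phases}, ERP onset day {events[pid].erp_onset_day}")


if __name__ == "__main__":
    main()
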