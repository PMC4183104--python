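"""Patient-level outcome statistics: who improves, and under what conditions?

Builds the cohort table (boundary-condition levels, motivation, max-mean
complexity score, relative outcome changes), then runs the hypothesis layer:
correlations of boundary conditions / instability / motivation with outcome,
the median-split 2x2 ANOVA (complexity x ward atmosphere) with post-hoc
tests, and the block-wise hierarchical regressions.
"""

import json
import pathlib

from dyncomp import pipeline
from dyncomp.core_data import load_events, load_factor_config, load_outcomes, load_ratings

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "statistics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fmap, scales = load_factor_config(ROOT / "cohort" / "factors.yaml")
    ratings = load_ratings(ROOT / "cohort" / "ratings.csv", scales)
    outcomes = load_outcomes(ROOT / "cohort" / "outcomes.csv")
    events = load_events(ROOT / "cohort" / "events.csv")

    table = pipeline.build_cohort_table(ratings, outcomes, events, fmap)
    table.to_csv(OUT / "cohort_table.csv")
    stats = pipeline.run_statistics(table)
    with open(OUT / "statistics.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=pipeline._jsonify)

    print(f"cohort table ({len(table)} patients) and statistics -> {OUT}")
    for pair in ("ward_atmosphere~rel_ybocs_change", "instability~rel_tpq_change",
                 "motivation~rel_ybocs_change"):
        c = stats["correlations"][pair]
        print(f"  {pair}: r = {c['r']:.2f}, p = {c['p']:.3f} (n = {c['n']})")
    for outcome, entry in stats["anova"].items():
        inter = entry["effects"]["a:b"]
        cells = entry["cell_means"]
        best = min(cells, key=cells.get)
        print(f"  ANOVA on {outcome}: interaction F(1,{inter['df_den']}) = "
              f"{inter['F']:.2f}, p = {inter['p']:.3f}; "
              f"largest improvement in the {best} cell ({cells[best]:.1f}%)")
    for outcome, blocks in stats["regression"].items():
        frame = pipeline.table3_frame(blocks)
        frame.to_csv(OUT / f"regression_{outcome}.csv", index=False)
        full = blocks[-1]
        print(f"  regression on {outcome}: full-model R^2 = {full['r_squared']:.3f} "
              f"(n = {full['n']})")


if __name__ == "__main__":
    main()
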