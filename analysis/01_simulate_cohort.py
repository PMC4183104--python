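"""Generate the working synthetic cohort: 23 OCD patients in day treatment.

Each patient contributes ~60 daily self-ratings on 47 items (5 factors),
twice-weekly Y-BOCS outcome assessments coupled to a latent symptom state
with one programmed order transition, and event metadata (18 of 23 undergo
exposure with response prevention, with onset 4-7 days after the transition).
Writes ratings/outcomes/events/factor config plus the ground truth to
results/cohort/.
"""

import json
import pathlib

import pandas as pd
from dataclasses import asdict

from dyncomp.core_data import write_events, write_factor_config, write_outcomes, write_ratings
from dyncomp.simulate import CohortConfig, config_to_dict, simulate_cohort

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 2014


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED)
    bundle = simulate_cohort(config)

    write_ratings(bundle.ratings, OUT / "ratings.csv")
    write_outcomes(bundle.outcomes, OUT / "outcomes.csv")
    write_events(bundle.events, OUT / "events.csv")
    write_factor_config(bundle.factor_map, bundle.scales, OUT / "factors.yaml")
    pd.DataFrame([asdict(t) for t in bundle.truths]).to_csv(OUT / "truth.csv", index=False)
    with open(OUT / "config.json", "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)

    durations = [t.duration for t in bundle.truths]
    n_erp = sum(t.erp_onset is not None for t in bundle.truths)
    print(f"wrote cohort of {config.n_patients} patients to {OUT}")
    print(f"  treatment duration: mean {sum(durations)/len(durations):.1f} days "
          f"(range {min(durations)}-{max(durations)})")
    print(f"  ERP participants: {n_erp} of {config.n_patients}")


if __name__ == "__main__":
    main()
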