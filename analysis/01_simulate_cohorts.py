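#!/usr/bin/env python
"""Generate the two synthetic study samples.

Draws the calibrated inter-method cohort (n = 90: demographics, six skinfold
sites, %BF by the two skinfold equations, BIA and DXA) and the observer-
reliability sample (n = 59 subjects x 3 passes x triplicate readings), and
writes them in the pipeline's CSV schemas under results/synthetic/.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

import dataclasses
from pathlib import Path

from sfconcord import io as sfio
from sfconcord import simulate

SEED = 20120901  # study-period-derived constant; any integer works
OUT = Path("results/synthetic")


def main() -> None:
    cohort = simulate.generate_cohort(simulate.CohortConfig(seed=SEED))
    rel_cohort = simulate.generate_cohort(simulate.reliability_cohort_config(seed=SEED + 1))
    sessions = simulate.generate_observer_sessions(
        rel_cohort.profiles, simulate.ObserverErrorConfig(seed=SEED + 2)
    )
    sfio.write_csv(sfio.subjects_frame(cohort), OUT / "subjects.csv")
    sfio.write_csv(sfio.subjects_frame(rel_cohort), OUT / "reliability_subjects.csv")
    sfio.write_csv(sfio.sessions_frame(sessions), OUT / "sessions.csv")
    sfio.write_manifest(
        OUT / "simulate_manifest.yaml",
        stage="simulate",
        seed=SEED,
        n_subjects=cohort.config.n_subjects,
        n_reliability=rel_cohort.config.n_subjects,
        cohort_config={
            k: v for k, v in dataclasses.asdict(cohort.config).items()
            if not isinstance(v, dict) or k in ("method_offsets", "method_noise_sd")
        },
    )
    print(f"wrote inter-method cohort (n={cohort.config.n_subjects}) and "
          f"reliability sessions (n={rel_cohort.config.n_subjects} x 3 passes) to {OUT}/")


if __name__ == "__main__":
    main()
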