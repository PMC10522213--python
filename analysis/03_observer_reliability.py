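#!/usr/bin/env python
"""Inter- and intra-observer reliability of the triplicate skinfold sessions.

Loads the synthetic observer sessions, computes Lin concordance coefficients
for observer A vs observer B (inter) and observer A's first vs second pass
(intra) over the three sites, the three-site sum and the derived percent
body fat, prints the reliability table and writes results/reliability/.

Run after 01_simulate_cohorts.py:  python analysis/03_observer_reliability.py
"""

from pathlib import Path

from sfconcord import io as sfio
from sfconcord import pipeline

SEED = 20120901
OUT = Path("results/reliability")


def main() -> None:
    sessions, s_issues = sfio.load_sessions("results/synthetic/sessions.csv")
    records, _ = sfio.load_subjects("results/synthetic/reliability_subjects.csv")
    cfg = pipeline.RunConfig(seed=SEED)
    run = pipeline.run_reliability(sessions, records, cfg)
    pipeline.emit_reliability(run, OUT, cfg)

    rep = run.report
    print(f"subjects analysed: {rep.n_subjects} (dropped {rep.n_dropped})")
    print("\nLin CCC (95% CI) by quantity and comparison:")
    for row in run.agreement.itertuples(index=False):
        print(f"  {row.quantity:14s} {row.comparison:6s} "
              f"{row.ccc:7.4f}  [{row.ci_lower:7.4f}, {row.ci_upper:7.4f}]")
    inter = run.agreement.query("comparison == 'inter'").set_index("quantity")["ccc"]
    best = inter[["triceps", "suprailiac", "medial_thigh"]].idxmax()
    print(f"\nbest inter-observer site: {best}")
    print(f"reports written to {OUT}/")


if __name__ == "__main__":
    main()
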