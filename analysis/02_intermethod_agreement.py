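#!/usr/bin/env python
"""Inter-method agreement analysis on the synthetic cohort.

Loads results/synthetic/subjects.csv, computes the descriptive table, the
paired differences of each method against DXA, Lin concordance coefficients
for the four non-reference pairs, St. Laurent gold-standard coefficients for
the three DXA-referenced pairs and Bland-Altman summaries for all seven
pairs, then prints the headline findings and writes the report CSVs under
results/intermethod/.

Run after 01_simulate_cohorts.py:  python analysis/02_intermethod_agreement.py
"""

from pathlib import Path

from sfconcord import io as sfio
from sfconcord import pipeline

SEED = 20120901
IN = Path("results/synthetic/subjects.csv")
OUT = Path("results/intermethod")


def main() -> None:
    records, issues = sfio.load_subjects(IN)
    cfg = pipeline.RunConfig(seed=SEED, reproduction_mode=True)  # 2-SD agreement limits
    report = pipeline.run_intermethod(records, cfg)
    pipeline.emit_intermethod(report, OUT, cfg)

    means = report.descriptives.set_index("variable")["mean"]
    print(f"complete cases: {report.n} ({len([i for i in issues if i.excluded])} excluded)")
    print("\nmean %BF by method:")
    for var in ("pbf_dxa", "pbf_bia", "pbf_jpw", "pbf_pet"):
        print(f"  {var:8s} {means[var]:6.2f}")
    print("\npaired differences vs DXA (mean, p):")
    for row in report.paired_tests.itertuples(index=False):
        print(f"  {row.comparison:16s} {row.mean_diff:7.2f}   p = {row.p_value:.2e}")
    print("\nagreement coefficients (95% CI):")
    for row in report.agreement.itertuples(index=False):
        print(f"  {row.statistic_kind:10s} {row.pair_label:22s} "
              f"{row.estimate:6.3f}  [{row.ci_lower:6.3f}, {row.ci_upper:6.3f}]")
    print(f"\nreports written to {OUT}/")


if __name__ == "__main__":
    main()
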