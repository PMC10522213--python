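#!/usr/bin/env python
"""ICC precision-based sample-size planning table.

How many subjects are needed so that the 95% CI of an intraclass correlation
has width at most w?  Tabulates Bonett's approximation over plausible ICC
values and rater counts, anchored at the study's planning point (ICC 0.70,
width 0.20).  Writes results/planning/icc_sample_size.csv.

Run from the repository root:  python analysis/04_sample_size_planning.py
"""

from pathlib import Path

import pandas as pd

from sfconcord.agreement import icc_sample_size

OUT = Path("results/planning")


def main() -> None:
    rows = [
        {"icc": rho, "ci_width": w, "raters": k, "n_required": icc_sample_size(rho, w, k)}
        for rho in (0.60, 0.70, 0.80, 0.90)
        for w in (0.10, 0.20)
        for k in (2, 3)
    ]
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "icc_sample_size.csv", index=False)
    anchor = df.query("icc == 0.70 and ci_width == 0.20 and raters == 2")["n_required"].item()
    print(df.to_string(index=False))
    print(f"\nplanning anchor: ICC 0.70, width 0.20, 2 raters -> n = {anchor}")
    print(f"table written to {OUT}/icc_sample_size.csv")


if __name__ == "__main__":
    main()
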