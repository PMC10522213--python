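# sfconcord

Method-agreement analysis for body-fat estimation in adult women: do
skinfold prediction equations and bioelectrical impedance (BIA) give the
same percent body fat (%BF) as dual-energy X-ray absorptiometry (DXA), and
how reproducible are skinfold measurements between and within observers?

The package implements, as a tested pipeline over synthetic cohorts:

* **Skinfold anthropometry** — body density *D* from two sex-specific
  equations: the three-site quadratic
  `D = 1.0994921 − 0.0009929·S₃ + 0.0000023·S₃² − 0.0001392·age`
  with S₃ = triceps + suprailiac + medial thigh (mm), and the four-site
  `D = 1.1954713 − 0.07513507·log₁₀(S₄) − 0.00041072·age`
  with S₄ = average axillary + suprailiac + medial thigh + medial calf;
  then the Siri conversion `%BF = 495/D − 450`.
* **Agreement statistics** — Lin's concordance correlation coefficient
  ρ̂_c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with a Fisher-z confidence
  interval; the St. Laurent gold-standard coefficient
  r̂_G = S_GG / (S_GG + S_DD) for comparing a method against DXA (S_DD is the
  uncentred sum of squared deviations, so systematic bias is penalised) with
  a seeded bootstrap CI; Bland-Altman bias and limits of agreement
  bias ± m·SD(diff) with CIs; paired t / Wilcoxon tests; and Bonett's
  ICC-precision sample-size formula.
* **Observer reliability** — Lin CCCs for observer A vs B (inter) and
  A's first vs second pass (intra) over triplicate site readings, propagated
  through the three-site sum, density and %BF.
* **Synthetic cohorts** — seeded generators calibrated to the published
  summary statistics of the study samples (n = 90 inter-method, n = 59
  reliability), since the raw subject data are not deposited.

## Worked example

```python
import numpy as np
import sfconcord as sc

d = sc.density_jpw(90.16, 29.06)          # cohort-mean inputs
pbf = sc.siri_percent_fat(d)
print(round(d.value, 7), round(pbf.value, 2))

est = sc.lin_ccc(sc.PairedSample(np.array([1., 2, 3]), np.array([2., 3, 4])))
print(round(est.coefficient, 4))
print(sc.st_laurent_coefficient([1, 2, 3], [2, 3, 4]))
print(sc.icc_sample_size(rho=0.70, ci_width=0.20, k=2))
```

prints

```
1.0246234 33.1
0.5714
0.4
101
```

— a woman with the cohort-mean skinfold sum and age has predicted density
≈ 1.0246 and ≈ 33.1 %BF; a method that reads exactly one unit high on the
1-2-3 scale has CCC 4/7 ≈ 0.571 and gold-standard agreement 0.4; and
observing an ICC of 0.70 with a 95% CI no wider than 0.20 needs 101 subjects
with two raters.

## The analysis

Numbered drivers under `analysis/` run the full study on synthetic data and
write CSV tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py      # calibrated cohorts + observer sessions
python analysis/02_intermethod_agreement.py # descriptives, paired tests, CCC/St. Laurent, Bland-Altman
python analysis/03_observer_reliability.py  # inter-/intra-observer CCC table
python analysis/04_sample_size_planning.py  # ICC precision planning table
```

On the calibrated cohort, DXA reads highest (all paired p < 0.01 against the
other three methods), intra-observer concordance exceeds inter-observer
concordance for every quantity, and the triceps is the most reproducible
site between observers — the qualitative findings of the study the
calibration emulates.

The same stages are available as a CLI (`sfconcord simulate | intermethod |
reliability | report`) for running on real CSV data in the schemas described
in `sfconcord.io`.

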