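"""Method-agreement and reliability statistics.

The statistics here answer "do two measurement methods give the same number
on the same subject?", which correlation alone cannot:

* Lin's concordance correlation coefficient (CCC) — Pearson precision times a
  bias-correction accuracy factor C_b; 1 means all points lie on the identity
  line.  Confidence intervals use the Fisher z-transform with Lin's asymptotic
  variance (the corrected form of the 1989 derivation).
* The St. Laurent gold-standard coefficient — for comparing an approximate
  method against a reference: the ratio of gold-standard variability to
  gold-standard variability plus squared method deviations, so both random
  error and systematic bias of the test method reduce agreement.  The point
  estimator is a variance ratio and lives in [0, 1]; its CI is a seeded
  percentile bootstrap.
* Bland-Altman analysis — bias (mean difference) and limits of agreement
  bias ± multiplier·SD(diff), with approximate CIs for bias and limits.
* A paired difference test (two-sided paired t by default, Wilcoxon
  signed-rank as an alternative).
* Bonett's precision formula for ICC sample-size planning.

Moment conventions: Lin's CCC uses n-denominator (biased) variances and
covariance, matching the original derivation; descriptive and Bland-Altman
SDs use the usual n-1 denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class AgreementError(ValueError):
    """Raised when an agreement statistic is undefined for the given input."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PairedSample:
    """Two aligned measurement vectors on the same subjects, no missing values."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise AgreementError("x and y must be 1-d vectors of equal length")
        if x.size < 3:
            raise AgreementError(f"need n >= 3 pairs, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise AgreementError("paired sample contains non-finite values; drop upstream")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class AgreementEstimate:
    """A concordance/agreement coefficient with its 95% CI.

    ``components`` carries (pearson_r, bias_correction_factor) for Lin's CCC.
    """

    coefficient: float
    ci_lower: float
    ci_upper: float
    n: int
    statistic_kind: str  # "lin_ccc" | "st_laurent"
    components: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise AgreementError(f"|coefficient| > 1: {self.coefficient}")
        if not (self.ci_lower - 1e-12 <= self.coefficient <= self.ci_upper + 1e-12):
            raise AgreementError(
                f"CI [{self.ci_lower}, {self.ci_upper}] does not bracket {self.coefficient}"
            )


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Bias, SD of differences and limits of agreement for one method pair."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    multiplier: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    n: int
    averages: np.ndarray  # per-pair (x+y)/2, for plotting
    differences: np.ndarray  # per-pair x-y


@dataclass(frozen=True)
class DescriptiveSummary:
    """Mean, SD (n-1), min, median, max and n of one variable."""

    mean: float
    sd: float
    minimum: float
    median: float
    maximum: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    sd_diff: float
    statistic: float
    df: Optional[float]
    p_value: float
    test: str  # "t" | "wilcoxon"


# ---------------------------------------------------------------------------
# operations


def descriptive_summary(values: Sequence[float]) -> DescriptiveSummary:
    """Mean, sample SD, min, median and max of a vector.

    A single observation yields SD 0 with an undefined-variance warning; the
    median of an even-length vector is the average of the central order
    statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise AgreementError("cannot summarise an empty vector")
    if not np.all(np.isfinite(v)):
        raise AgreementError("vector contains non-finite values")
    if v.size == 1:
        warnings.warn("sample SD undefined for n = 1; reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(v, ddof=1))
    return DescriptiveSummary(
        mean=float(np.mean(v)),
        sd=sd,
        minimum=float(np.min(v)),
        median=float(np.median(v)),
        maximum=float(np.max(v)),
        n=int(v.size),
    )


def pearson_r(sample: PairedSample) -> float:
    """Product-moment correlation; errors on zero variance."""
    x, y = sample.x, sample.y
    if np.var(x) == 0 or np.var(y) == 0:
        raise AgreementError("correlation undefined: a vector has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _ccc_point(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(rho_c, r, u, c_b) from n-denominator moments.

    c_b = rho_c / r simplifies to 2 s_x s_y / (s_x^2 + s_y^2 + (mean_x -
    mean_y)^2), which stays defined even when the correlation is exactly 0.
    """
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))  # biased
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    if sx2 == 0 or sy2 == 0:
        raise AgreementError("CCC undefined: a vector has zero variance")
    denom = sx2 + sy2 + (mx - my) ** 2
    rho_c = 2.0 * sxy / denom
    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location shift relative to scale
    c_b = 2.0 * math.sqrt(sx2 * sy2) / denom
    return rho_c, r, u, c_b


def lin_ccc(sample: PairedSample, alpha: float = 0.05) -> AgreementEstimate:
    """Lin's concordance correlation coefficient with a z-transform CI.

    Point estimate: rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)
    with n-denominator moments.  CI: Z = atanh(rho_c), variance

        sigma_Z^2 = (1/(n-2)) * [ (1-r^2) rho_c^2 / ((1-rho_c^2) r^2)
                                  + 4 rho_c^3 (1-rho_c) u^2 / (r (1-rho_c^2)^2)
                                  - 2 rho_c^4 u^4 / (r^2 (1-rho_c^2)^2) ],

    with u the standardised location shift, back-transformed through tanh.
    A degenerate |rho_c| = 1 returns a point-mass CI with a warning.
    """
    if not (0 < alpha < 1):
        raise AgreementError(f"alpha must be in (0, 1), got {alpha}")
    x, y = sample.x, sample.y
    rho_c, r, u, cb = _ccc_point(x, y)
    n = sample.n
    if abs(rho_c) >= 1.0 - 1e-15:
        warnings.warn("CCC is ±1; CI degenerates to a point", stacklevel=2)
        return AgreementEstimate(rho_c, rho_c, rho_c, n, "lin_ccc", (r, cb))
    z = math.atanh(rho_c)
    one_m = 1.0 - rho_c * rho_c
    # terms written via c_b = rho_c / r so that r = 0 is not a singularity
    var_z = (
        (1.0 - r * r) * cb * cb / one_m
        + 4.0 * rho_c * rho_c * cb * (1.0 - rho_c) * u * u / (one_m * one_m)
        - 2.0 * rho_c * rho_c * cb * cb * u**4 / (one_m * one_m)
    ) / (n - 2)
    se = math.sqrt(max(var_z, 0.0))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = math.tanh(z - zq * se), math.tanh(z + zq * se)
    return AgreementEstimate(rho_c, lo, hi, n, "lin_ccc", (r, cb))


def st_laurent_coefficient(gold: Sequence[float], test: Sequence[float]) -> float:
    """Point estimate of the gold-standard agreement coefficient.

    With D_i = test_i - gold_i:  r_G = S_GG / (S_GG + S_DD), where S_GG is the
    centred sum of squares of the gold standard and S_DD = sum(D_i^2) is
    *uncentred*, so a systematic bias of the test method penalises agreement.
    Lies in [0, 1]; equals 1 iff test == gold elementwise.
    """
    g = np.asarray(gold, dtype=float)
    t = np.asarray(test, dtype=float)
    if g.shape != t.shape or g.ndim != 1:
        raise AgreementError("gold and test must be aligned 1-d vectors")
    s_gg = float(np.sum((g - g.mean()) ** 2))
    if s_gg == 0:
        raise AgreementError("gold standard has zero variance")
    s_dd = float(np.sum((t - g) ** 2))
    return s_gg / (s_gg + s_dd)


def st_laurent(
    gold: Sequence[float],
    test: Sequence[float],
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> AgreementEstimate:
    """Gold-standard agreement coefficient with a percentile-bootstrap CI.

    Pairs are resampled with replacement ``n_boot`` times (seeded); bootstrap
    replicates whose resampled gold vector is constant are redrawn implicitly
    by being skipped.
    """
    g = np.asarray(gold, dtype=float)
    t = np.asarray(test, dtype=float)
    if g.size < 3:
        raise AgreementError(f"need n >= 3 pairs, got {g.size}")
    est = st_laurent_coefficient(g, t)
    rng = np.random.default_rng(seed)
    n = g.size
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        gb = g[idx]
        if np.ptp(gb) == 0:  # degenerate resample: no gold variance
            continue
        reps.append(st_laurent_coefficient(gb, t[idx]))
    if not reps:
        raise AgreementError("all bootstrap resamples degenerate")
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    # percentile interval may exclude the point estimate for extreme skew;
    # clamp so the reported triple stays internally consistent
    lo, hi = min(float(lo), est), max(float(hi), est)
    return AgreementEstimate(est, lo, hi, int(n), "st_laurent")


def bland_altman(
    sample: PairedSample, multiplier: float = 1.96, alpha: float = 0.05
) -> BlandAltmanSummary:
    """Bland-Altman bias and limits of agreement for differences x - y.

    LoA = bias ± multiplier·SD(diff).  The bias CI uses the exact t interval;
    the LoA CIs use the approximate SE(LoA) = SD·sqrt(1/n + multiplier^2 /
    (2(n-1))) with t quantiles.  Also returns the per-pair (average,
    difference) points needed to draw the plot.
    """
    d = sample.x - sample.y
    a = (sample.x + sample.y) / 2.0
    n = sample.n
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo = bias - multiplier * sd
    hi = bias + multiplier * sd
    tq = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1.0 / n + multiplier * multiplier / (2.0 * (n - 1)))
    return BlandAltmanSummary(
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        multiplier=multiplier,
        ci_bias=(bias - tq * se_bias, bias + tq * se_bias),
        ci_loa_lower=(lo - tq * se_loa, lo + tq * se_loa),
        ci_loa_upper=(hi - tq * se_loa, hi + tq * se_loa),
        n=n,
        averages=a,
        differences=d,
    )


def paired_difference_test(sample: PairedSample, test: str = "t") -> PairedTestResult:
    """Two-sided paired test on x - y ("t" or "wilcoxon").

    Zero-variance differences make both tests degenerate and raise.
    """
    d = sample.x - sample.y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise AgreementError("paired test degenerate: differences have zero variance")
    if test == "t":
        res = stats.ttest_rel(sample.x, sample.y)
        return PairedTestResult(
            mean_diff=float(np.mean(d)),
            sd_diff=sd,
            statistic=float(res.statistic),
            df=float(sample.n - 1),
            p_value=float(res.pvalue),
            test="t",
        )
    if test == "wilcoxon":
        res = stats.wilcoxon(sample.x, sample.y)
        return PairedTestResult(
            mean_diff=float(np.mean(d)),
            sd_diff=sd,
            statistic=float(res.statistic),
            df=None,
            p_value=float(res.pvalue),
            test="wilcoxon",
        )
    raise AgreementError(f"unknown paired test {test!r}")


def icc_sample_size(rho: float, ci_width: float, k: int = 2, alpha: float = 0.05) -> int:
    """Subjects needed so the ICC's (1-alpha) CI has width <= ci_width.

    Bonett's precision approximation with k raters:

        n = ceil(1 + 8 z^2 (1-rho)^2 [1+(k-1) rho]^2 / (k (k-1) w^2)).

    Conservative: the real-valued solution is rounded up.
    """
    if not (0 < rho < 1):
        raise AgreementError(f"rho must be in (0, 1), got {rho}")
    if ci_width <= 0:
        raise AgreementError(f"ci_width must be positive, got {ci_width}")
    if k < 2:
        raise AgreementError(f"need k >= 2 raters, got {k}")
    if not (0 < alpha < 1):
        raise AgreementError(f"alpha must be in (0, 1), got {alpha}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n = 1.0 + 8.0 * z * z * (1.0 - rho) ** 2 * (1.0 + (k - 1) * rho) ** 2 / (
        k * (k - 1) * ci_width * ci_width
    )
    return int(math.ceil(n))
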