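"""End-to-end orchestration of the inter-method and reliability analyses.

The inter-method stage reproduces the published analysis layout: a
descriptive table over all measured and derived variables, paired-difference
tests of each method against DXA, Lin CCCs for the four non-reference pairs,
St. Laurent gold-standard coefficients for the three DXA-referenced pairs,
and Bland-Altman summaries plus plot data for all seven pairs.  The
reliability stage wraps the observer analysis and adds its descriptive table.

All randomness (the St. Laurent bootstrap) is driven by the run config seed;
fixed inputs plus a fixed seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sfio
from .agreement import (
    AgreementEstimate,
    AgreementError,
    BlandAltmanSummary,
    PairedSample,
    PairedTestResult,
    bland_altman,
    descriptive_summary,
    lin_ccc,
    paired_difference_test,
    st_laurent,
)
from .anthro import Protocol, density_jpw, density_pet, siri_percent_fat, sum_skinfolds
from .reliability import (
    COMPARISONS,
    QUANTITIES,
    ObserverSession,
    ReliabilityReport,
    reliability_analysis,
)

logger = logging.getLogger(__name__)

#: The seven inter-method pairs, as (variable_x, variable_y) over the derived
#: per-subject table; order follows the published figure panels.
INTERMETHOD_PAIRS: tuple[tuple[str, str], ...] = (
    ("pbf_jpw", "pbf_pet"),
    ("sum_jpw", "sum_pet"),
    ("pbf_jpw", "pbf_dxa"),
    ("pbf_pet", "pbf_dxa"),
    ("pbf_bia", "pbf_dxa"),
    ("pbf_jpw", "pbf_bia"),
    ("pbf_pet", "pbf_bia"),
)

#: Pairs scored with Lin's CCC (no reference method involved).
LIN_PAIRS = (
    ("pbf_jpw", "pbf_pet"),
    ("sum_jpw", "sum_pet"),
    ("pbf_jpw", "pbf_bia"),
    ("pbf_pet", "pbf_bia"),
)

#: Methods scored against DXA with the gold-standard coefficient.
GOLD_PAIRS = (("pbf_jpw", "pbf_dxa"), ("pbf_pet", "pbf_dxa"), ("pbf_bia", "pbf_dxa"))

#: Columns of the descriptive table, in publication order.
DESCRIPTIVE_VARS = (
    "age_years",
    "weight_kg",
    "height_m",
    "bmi_kg_m2",
    "aasf_mm",
    "tsf_mm",
    "sisf_mm",
    "mtsf_mm",
    "csf_mm",
    "sum_jpw",
    "sum_pet",
    "density_jpw",
    "density_pet",
    "pbf_jpw",
    "pbf_pet",
    "pbf_dxa",
    "pbf_bia",
)


@dataclass(frozen=True)
class RunConfig:
    """Statistical options for one pipeline run.

    ``reproduction_mode`` applies the publication's conventions: limits of
    agreement at 2 SDs (the figures state "two SDs from the mean") instead of
    the 1.96 default.
    """

    alpha: float = 0.05
    ba_multiplier: float = 1.96
    n_boot: int = 2000
    seed: int = 0
    paired_test: str = "t"  # "t" | "wilcoxon"
    reproduction_mode: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.n_boot < 100:
            raise ValueError(f"need >= 100 bootstrap replicates, got {self.n_boot}")

    @property
    def multiplier(self) -> float:
        return 2.0 if self.reproduction_mode else self.ba_multiplier


@dataclass(frozen=True)
class IntermethodReport:
    descriptives: pd.DataFrame
    paired_tests: pd.DataFrame
    agreement: pd.DataFrame
    bland_altman: Mapping[tuple[str, str], BlandAltmanSummary]
    derived: pd.DataFrame  # per-subject derived variables
    n: int


def derive_variables(records: Sequence[sfio.SubjectRecord]) -> pd.DataFrame:
    """Per-subject derived table: sums, densities and %BF by all four methods.

    Subjects missing any value needed by the inter-method pair set (a required
    skinfold site, BIA or DXA) are excluded here with a log entry, so every
    downstream pair sees the same complete-case sample.
    """
    rows = []
    dropped = 0
    for rec in records:
        try:
            s3 = sum_skinfolds(rec.profile, Protocol.JPW)
            s4 = sum_skinfolds(rec.profile, Protocol.PET)
        except Exception as exc:
            logger.warning("excluding %s: %s", rec.subject.subject_id, exc)
            dropped += 1
            continue
        if rec.bia_pbf is None or rec.dxa_pbf is None:
            logger.warning("excluding %s: missing BIA or DXA value", rec.subject.subject_id)
            dropped += 1
            continue
        d3 = density_jpw(s3, rec.subject.age_years)
        d4 = density_pet(s4, rec.subject.age_years)
        rows.append(
            {
                "subject_id": rec.subject.subject_id,
                "age_years": rec.subject.age_years,
                "weight_kg": rec.subject.weight_kg,
                "height_m": rec.subject.height_m,
                "bmi_kg_m2": rec.subject.bmi_kg_m2,
                "tsf_mm": rec.profile.triceps_mm,
                "sisf_mm": rec.profile.suprailiac_mm,
                "aasf_mm": rec.profile.average_axillary_mm,
                "mtsf_mm": rec.profile.medial_thigh_mm,
                "csf_mm": rec.profile.medial_calf_mm,
                "sum_jpw": s3,
                "sum_pet": s4,
                "density_jpw": d3.value,
                "density_pet": d4.value,
                "pbf_jpw": siri_percent_fat(d3).value,
                "pbf_pet": siri_percent_fat(d4).value,
                "pbf_bia": rec.bia_pbf,
                "pbf_dxa": rec.dxa_pbf,
            }
        )
    if dropped:
        logger.warning("derive_variables excluded %d record(s)", dropped)
    return pd.DataFrame(rows)


def run_intermethod(
    records: Sequence[sfio.SubjectRecord], config: RunConfig = RunConfig()
) -> IntermethodReport:
    """Full inter-method analysis over validated subject records."""
    derived = derive_variables(records)
    n = len(derived)
    if n < 3:
        raise AgreementError(f"need >= 3 complete cases for inter-method analysis, got {n}")

    desc_rows = []
    for var in DESCRIPTIVE_VARS:
        if var not in derived.columns or derived[var].isna().all():
            continue
        s = descriptive_summary(derived[var].dropna().to_numpy())
        desc_rows.append(
            {"variable": var, "mean": s.mean, "sd": s.sd, "minimum": s.minimum,
             "median": s.median, "maximum": s.maximum, "n": s.n}
        )
    descriptives = pd.DataFrame(desc_rows)

    test_rows = []
    for var in ("pbf_jpw", "pbf_pet", "pbf_bia"):
        sample = PairedSample(
            derived[var].to_numpy(), derived["pbf_dxa"].to_numpy(), labels=(var, "pbf_dxa")
        )
        d = sample.x - sample.y
        try:
            res: PairedTestResult = paired_difference_test(sample, test=config.paired_test)
            row = {"mean_diff": res.mean_diff, "sd_diff": res.sd_diff, "statistic": res.statistic,
                   "df": res.df, "p_value": res.p_value, "test": res.test}
        except AgreementError as exc:  # identical methods: test degenerate, not fatal
            logger.warning("paired test %s vs DXA degenerate: %s", var, exc)
            row = {"mean_diff": float(np.mean(d)), "sd_diff": 0.0, "statistic": np.nan,
                   "df": np.nan, "p_value": np.nan, "test": f"{config.paired_test} (degenerate)"}
        test_rows.append({"comparison": f"{var}_vs_dxa", **row})
    paired_tests = pd.DataFrame(test_rows)

    agree_rows = []
    rng = np.random.default_rng(config.seed)
    for vx, vy in LIN_PAIRS:
        est = lin_ccc(
            PairedSample(derived[vx].to_numpy(), derived[vy].to_numpy(), labels=(vx, vy)),
            alpha=config.alpha,
        )
        agree_rows.append(_agree_row("lin_ccc", vx, vy, est))
    for vx, vy in GOLD_PAIRS:
        # DXA is always the gold argument; coefficient orientation is fixed
        est = st_laurent(
            derived[vy].to_numpy(),
            derived[vx].to_numpy(),
            alpha=config.alpha,
            n_boot=config.n_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        agree_rows.append(_agree_row("st_laurent", vx, vy, est))
    agreement = pd.DataFrame(agree_rows)

    ba = {}
    for vx, vy in INTERMETHOD_PAIRS:
        ba[(vx, vy)] = bland_altman(
            PairedSample(derived[vx].to_numpy(), derived[vy].to_numpy(), labels=(vx, vy)),
            multiplier=config.multiplier,
            alpha=config.alpha,
        )
    return IntermethodReport(descriptives, paired_tests, agreement, ba, derived, n)


def _agree_row(kind: str, vx: str, vy: str, est: AgreementEstimate) -> dict:
    return {
        "statistic_kind": kind,
        "pair_label": f"{vx}_vs_{vy}",
        "n": est.n,
        "estimate": est.coefficient,
        "ci_lower": est.ci_lower,
        "ci_upper": est.ci_upper,
    }


@dataclass(frozen=True)
class ReliabilityRun:
    report: ReliabilityReport
    descriptives: pd.DataFrame  # per (quantity, pass) summary, publication analog
    agreement: pd.DataFrame  # tidy CCC table


def run_reliability(
    sessions: Sequence[ObserverSession],
    records: Sequence[sfio.SubjectRecord],
    config: RunConfig = RunConfig(),
) -> ReliabilityRun:
    """Observer reliability analysis plus its descriptive table."""
    ages = {rec.subject.subject_id: rec.subject.age_years for rec in records}
    report = reliability_analysis(sessions, ages, alpha=config.alpha)

    from .reliability import PASSES, RELIABILITY_SITES, session_derivatives

    by_subject: dict[str, dict[str, ObserverSession]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, {})[s.observer_pass] = s
    desc_rows = []
    per_pass_values: dict[tuple[str, str], list[float]] = {}
    for sid in sorted(by_subject):
        passes = by_subject[sid]
        if set(PASSES) - set(passes) or sid not in ages:
            continue
        for p in PASSES:
            try:
                s3, dens, pbf = session_derivatives(passes[p], ages[sid])
            except Exception:
                continue
            vals = {site: passes[p].site_mean(site) for site in RELIABILITY_SITES}
            vals.update({"sum_sf": s3, "density": dens, "percent_bf": pbf})
            for q, v in vals.items():
                per_pass_values.setdefault((q, p), []).append(v)
    for (q, p), vals in sorted(per_pass_values.items()):
        s = descriptive_summary(vals)
        desc_rows.append(
            {"quantity": q, "observer_pass": p, "mean": s.mean, "sd": s.sd,
             "minimum": s.minimum, "median": s.median, "maximum": s.maximum, "n": s.n}
        )
    descriptives = pd.DataFrame(desc_rows)

    tidy = []
    for q in QUANTITIES:
        for comp in COMPARISONS:
            est = report.estimates[(q, comp)]
            tidy.append(
                {"quantity": q, "comparison": comp, "n": est.n, "ccc": est.coefficient,
                 "ci_lower": est.ci_lower, "ci_upper": est.ci_upper}
            )
    return ReliabilityRun(report, descriptives, pd.DataFrame(tidy))


def emit_intermethod(report: IntermethodReport, outdir: str | Path, config: RunConfig) -> list[Path]:
    """Write the inter-method report: descriptive, test, agreement and
    Bland-Altman CSVs plus a manifest.  Idempotent for fixed inputs/seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = [
        sfio.write_csv(report.descriptives, outdir / "descriptives.csv"),
        sfio.write_csv(report.paired_tests, outdir / "paired_tests.csv"),
        sfio.write_csv(report.agreement, outdir / "agreement.csv"),
        sfio.write_csv(report.derived, outdir / "derived_variables.csv"),
    ]
    ba_lines = []
    for (vx, vy), ba in report.bland_altman.items():
        label = f"{vx}_vs_{vy}"
        pts = pd.DataFrame(
            {"subject_id": report.derived["subject_id"], "average": ba.averages,
             "difference": ba.differences}
        )
        written.append(sfio.write_csv(pts, outdir / f"bland_altman_{label}.csv"))
        ba_lines.append(
            {"pair_label": label, "n": ba.n, "bias": ba.bias, "sd_diff": ba.sd_diff,
             "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper, "multiplier": ba.multiplier,
             "ci_bias_lower": ba.ci_bias[0], "ci_bias_upper": ba.ci_bias[1],
             "ci_loa_lower_lo": ba.ci_loa_lower[0], "ci_loa_lower_hi": ba.ci_loa_lower[1],
             "ci_loa_upper_lo": ba.ci_loa_upper[0], "ci_loa_upper_hi": ba.ci_loa_upper[1]}
        )
    written.append(sfio.write_csv(pd.DataFrame(ba_lines), outdir / "bland_altman_summary.csv"))
    written.append(
        sfio.write_manifest(
            outdir / "manifest.yaml",
            stage="intermethod",
            n_complete_cases=report.n,
            alpha=config.alpha,
            ba_multiplier=config.multiplier,
            n_boot=config.n_boot,
            seed=config.seed,
            paired_test=config.paired_test,
            reproduction_mode=config.reproduction_mode,
        )
    )
    return written


def emit_reliability(run: ReliabilityRun, outdir: str | Path, config: RunConfig) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = [
        sfio.write_csv(run.descriptives, outdir / "observer_descriptives.csv"),
        sfio.write_csv(run.agreement, outdir / "reliability_ccc.csv"),
        sfio.write_manifest(
            outdir / "manifest.yaml",
            stage="reliability",
            n_subjects=run.report.n_subjects,
            n_dropped=run.report.n_dropped,
            alpha=config.alpha,
            seed=config.seed,
        ),
    ]
    return written
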