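"""Seeded synthetic cohorts with the statistical structure of the study sample.

The study's raw subject data are not deposited, so analyses and tests run on
simulated cohorts calibrated to the published summary tables:

* the inter-method sample (n = 90): ages, weight/height, and five skinfold
  sites drawn from a truncated multivariate normal matching the printed
  means/SDs, with percent body fat by the two skinfold equations computed
  through the prediction chain and DXA/BIA generated as a latent reference
  plus a method offset plus noise (DXA sits ~5.4 %BF above the three-site
  skinfold estimate, reproducing the printed ordering DXA > BIA ≈ JPW > PET);
* the reliability sample (n = 59): triplicate readings per site per observer
  pass, with small within-observer reading noise and a site-specific
  between-observer bias and random disagreement, largest at the suprailiac
  site.

Closed-form population values of the agreement coefficients under these
generating models are provided as oracles for parameter-recovery tests.
All draws come from a single ``numpy.random.Generator`` seeded in the config,
so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .anthro import (
    Method,
    PercentBodyFat,
    Protocol,
    SkinfoldProfile,
    Subject,
    percent_fat_from_profile,
)
from .reliability import RELIABILITY_SITES, ObserverSession


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: Site order used by the correlation matrix and sampling.
SITE_ORDER = (
    "triceps",
    "subscapular",
    "suprailiac",
    "average_axillary",
    "medial_thigh",
    "medial_calf",
)

# Published summary calibration (inter-method sample): mean, SD per site, mm.
# The subscapular site is not summarised in the source tables (no equation
# uses it); its parameters are uncalibrated placeholders.
DEFAULT_SITE_MEANS = {
    "triceps": 20.13,
    "subscapular": 20.0,
    "suprailiac": 25.07,
    "average_axillary": 17.64,
    "medial_thigh": 35.08,
    "medial_calf": 22.28,
}
DEFAULT_SITE_SDS = {
    "triceps": 6.81,
    "subscapular": 8.0,
    "suprailiac": 10.04,
    "average_axillary": 7.92,
    "medial_thigh": 10.39,
    "medial_calf": 7.42,
}

MIN_SITE_MM = 2.0  # truncation floor for generated site values
MAX_SITE_MM = 100.0


def exchangeable_correlation(k: int, rho: float) -> np.ndarray:
    """k x k matrix with 1 on the diagonal and rho off-diagonal."""
    if not (-1.0 / (k - 1) < rho < 1.0):
        raise ConfigError(f"exchangeable rho {rho} not positive definite for k={k}")
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


@dataclass(frozen=True)
class CohortConfig:
    """Distributional parameters of the synthetic inter-method cohort.

    Defaults reproduce the published cohort summaries: n = 90 women,
    age ~29 y, BMI ~27, site means/SDs as printed, an exchangeable
    between-site correlation of 0.6 (the publication gives no correlation
    structure; this is a config default, not a claim about the real cohort),
    DXA offset +5.4 %BF over the three-site skinfold estimate and BIA
    offset 0, with method noise SDs near the printed paired-difference SDs.
    """

    n_subjects: int = 90
    age_mean: float = 29.06
    age_sd: float = 4.96
    age_min: float = 18.33
    age_max: float = 37.77
    weight_mean_kg: float = 69.92
    weight_sd_kg: float = 15.98
    height_mean_m: float = 1.61
    height_sd_m: float = 0.05
    site_means_mm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_MEANS))
    site_sds_mm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_SDS))
    site_rho: float = 0.6
    site_correlation: Optional[np.ndarray] = None  # overrides site_rho if given
    method_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"DXA": 5.4, "BIA": 0.0}
    )
    method_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"DXA": 4.5, "BIA": 4.7}
    )
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(SITE_ORDER)
        if self.site_correlation is not None:
            c = np.asarray(self.site_correlation, dtype=float)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ConfigError(f"site_correlation must be symmetric {k}x{k}")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ConfigError("site_correlation is not positive definite")
            return c
        return exchangeable_correlation(k, self.site_rho)

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError(f"need n_subjects >= 3, got {self.n_subjects}")
        for site in SITE_ORDER:
            if site not in self.site_means_mm or site not in self.site_sds_mm:
                raise ConfigError(f"missing site parameters for {site!r}")
            if self.site_sds_mm[site] <= 0:
                raise ConfigError(f"site SD must be positive for {site!r}")
        if self.age_sd <= 0 or self.weight_sd_kg <= 0 or self.height_sd_m <= 0:
            raise ConfigError("age/weight/height SDs must be positive")
        if not (self.age_min < self.age_max):
            raise ConfigError("age_min must be below age_max")
        for m, sd in self.method_noise_sd.items():
            if sd < 0:
                raise ConfigError(f"method noise SD must be >= 0 for {m}")
        self.correlation_matrix()


@dataclass(frozen=True)
class MethodPanel:
    """One subject's percent body fat by each of the four methods."""

    subject_id: str
    sf_jpw: float
    sf_pet: float
    bia: float
    dxa: float

    def value(self, method: Method) -> float:
        return {
            Method.SF_JPW: self.sf_jpw,
            Method.SF_PET: self.sf_pet,
            Method.BIA: self.bia,
            Method.DXA: self.dxa,
        }[method]


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]
    profiles: tuple[SkinfoldProfile, ...]
    panels: tuple[MethodPanel, ...]
    config: CohortConfig


_REJECTION_CAP = 10_000


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; raises if the cap is exhausted."""
    out = np.empty(size)
    filled = 0
    for _ in range(_REJECTION_CAP):
        draw = rng.normal(mean, sd, size=size - filled)
        ok = draw[(draw > lo) & (draw < hi)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
        if filled == size:
            return out
    raise ConfigError(
        f"truncated-normal rejection cap exhausted (mean={mean}, sd={sd}, [{lo}, {hi}])"
    )


def _truncated_mvn_sites(rng: np.random.Generator, cfg: CohortConfig, n: int) -> np.ndarray:
    """n x 6 site draws, each row kept only if all sites fall in (2, 100) mm."""
    mu = np.array([cfg.site_means_mm[s] for s in SITE_ORDER])
    sd = np.array([cfg.site_sds_mm[s] for s in SITE_ORDER])
    cov = cfg.correlation_matrix() * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov)
    out = np.empty((n, len(SITE_ORDER)))
    filled = 0
    for _ in range(_REJECTION_CAP):
        z = rng.standard_normal((n - filled, len(SITE_ORDER)))
        draw = mu + z @ chol.T
        ok = draw[np.all((draw > MIN_SITE_MM) & (draw < MAX_SITE_MM), axis=1)]
        take = min(ok.shape[0], n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == n:
            return out
    raise ConfigError("site rejection-sampling cap exhausted; check configuration")


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort: subjects, skinfold profiles, method panels.

    Skinfold-derived %BF values are computed exactly through the prediction
    chain; DXA and BIA are the subject's three-site skinfold %BF (the latent
    reference) plus the configured method offset plus Gaussian noise.
    Reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    ages = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n)
    heights = _truncated_normal(rng, config.height_mean_m, config.height_sd_m, 1.30, 2.10, n)
    weights = _truncated_normal(rng, config.weight_mean_kg, config.weight_sd_kg, 35.0, 160.0, n)
    sites = _truncated_mvn_sites(rng, config, n)
    noise = {
        m: rng.normal(0.0, config.method_noise_sd.get(m, 0.0), size=n) for m in ("DXA", "BIA")
    }

    subjects, profiles, panels = [], [], []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        row = dict(zip(SITE_ORDER, sites[i]))
        subj = Subject(sid, float(ages[i]), float(weights[i]), float(heights[i]))
        prof = SkinfoldProfile(
            subject_id=sid,
            triceps_mm=row["triceps"],
            subscapular_mm=row["subscapular"],
            suprailiac_mm=row["suprailiac"],
            average_axillary_mm=row["average_axillary"],
            medial_thigh_mm=row["medial_thigh"],
            medial_calf_mm=row["medial_calf"],
        )
        jpw = percent_fat_from_profile(prof, subj.age_years, Protocol.JPW).value
        pet = percent_fat_from_profile(prof, subj.age_years, Protocol.PET).value
        dxa = jpw + config.method_offsets.get("DXA", 0.0) + float(noise["DXA"][i])
        bia = jpw + config.method_offsets.get("BIA", 0.0) + float(noise["BIA"][i])
        # keep generated panels inside the sanity band enforced downstream
        dxa = float(np.clip(dxa, -9.9, 79.9))
        bia = float(np.clip(bia, -9.9, 79.9))
        PercentBodyFat(dxa, Method.DXA), PercentBodyFat(bia, Method.BIA)  # validate
        subjects.append(subj)
        profiles.append(prof)
        panels.append(MethodPanel(sid, jpw, pet, bia, dxa))
    return Cohort(tuple(subjects), tuple(profiles), tuple(panels), config)


@dataclass(frozen=True)
class ObserverErrorConfig:
    """Observer-error model for the triplicate reliability sessions.

    Per site (mm): ``intra_noise_sd_mm`` is the iid reading noise applied to
    every triplicate reading of every pass; ``inter_bias_mm`` is observer B's
    systematic offset; ``inter_noise_sd_mm`` is observer B's subject-level
    random disagreement (drawn once per subject-site, shared by B's three
    readings).  Defaults are calibrated to the published reliability tables:
    the suprailiac site carries the largest inter-observer bias (+3.68 mm)
    and the triceps the smallest random disagreement, which makes triceps the
    best inter-observer site downstream.
    """

    intra_noise_sd_mm: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.1 for s in RELIABILITY_SITES}
    )
    inter_bias_mm: Mapping[str, float] = field(
        default_factory=lambda: {"triceps": -0.45, "suprailiac": 3.68, "medial_thigh": 0.19}
    )
    inter_noise_sd_mm: Mapping[str, float] = field(
        default_factory=lambda: {"triceps": 0.9, "suprailiac": 3.8, "medial_thigh": 4.7}
    )
    seed: int = 0

    def validate(self) -> None:
        for name, m in (
            ("intra_noise_sd_mm", self.intra_noise_sd_mm),
            ("inter_noise_sd_mm", self.inter_noise_sd_mm),
        ):
            for site, sd in m.items():
                if sd < 0:
                    raise ConfigError(f"{name}[{site!r}] must be >= 0, got {sd}")


MIN_READING_MM = 0.2  # caliper floor: generated readings never drop below this


def generate_observer_sessions(
    profiles: Sequence[SkinfoldProfile], err: ObserverErrorConfig
) -> list[ObserverSession]:
    """Three passes (A1, B, A2) of triplicate readings for every profile.

    Each reading = true site value + pass-level observer effect + iid reading
    noise; observer A's passes carry no systematic effect, observer B adds the
    configured site bias plus a per-subject random disagreement.  Readings are
    floored at the caliper resolution so they stay positive.
    """
    err.validate()
    rng = np.random.default_rng(err.seed)
    sessions: list[ObserverSession] = []
    for prof in profiles:
        true = {s: prof.site(s) for s in RELIABILITY_SITES}
        b_effect = {
            s: err.inter_bias_mm.get(s, 0.0)
            + rng.normal(0.0, err.inter_noise_sd_mm.get(s, 0.0))
            for s in RELIABILITY_SITES
        }
        for pass_name in ("A1", "B", "A2"):
            readings = {}
            for s in RELIABILITY_SITES:
                base = true[s] + (b_effect[s] if pass_name == "B" else 0.0)
                trip = base + rng.normal(0.0, err.intra_noise_sd_mm.get(s, 0.0), size=3)
                trip = np.maximum(trip, MIN_READING_MM)
                readings[s] = (float(trip[0]), float(trip[1]), float(trip[2]))
            sessions.append(ObserverSession(prof.subject_id, pass_name, readings))
    return sessions


def closed_form_ccc(mu1: float, mu2: float, sigma1: float, sigma2: float, rho: float) -> float:
    """Population Lin CCC of a bivariate normal with the given parameters.

    2*rho*sigma1*sigma2 / (sigma1^2 + sigma2^2 + (mu1 - mu2)^2); the oracle
    the sample CCC converges to on data generated from those parameters.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ConfigError("sigmas must be positive")
    if abs(rho) > 1:
        raise ConfigError(f"|rho| must be <= 1, got {rho}")
    return 2.0 * rho * sigma1 * sigma2 / (sigma1**2 + sigma2**2 + (mu1 - mu2) ** 2)


def closed_form_st_laurent(sigma_g: float, sigma_d: float, delta: float = 0.0) -> float:
    """Population gold-standard coefficient under test = gold + bias + noise.

    sigma_g^2 / (sigma_g^2 + sigma_d^2 + delta^2), with delta the mean bias
    and sigma_d the SD of the zero-mean part of the deviations.
    """
    if sigma_g <= 0:
        raise ConfigError("sigma_g must be positive")
    if sigma_d < 0:
        raise ConfigError("sigma_d must be >= 0")
    return sigma_g**2 / (sigma_g**2 + sigma_d**2 + delta**2)


def reliability_cohort_config(seed: int = 0) -> CohortConfig:
    """Cohort configuration matching the published reliability sample (n = 59)."""
    means = dict(DEFAULT_SITE_MEANS)
    sds = dict(DEFAULT_SITE_SDS)
    means.update({"triceps": 19.45, "suprailiac": 25.59, "medial_thigh": 34.37})
    sds.update({"triceps": 6.46, "suprailiac": 11.20, "medial_thigh": 9.89})
    return CohortConfig(
        n_subjects=59,
        age_mean=29.28,
        age_sd=4.79,
        age_min=19.78,
        age_max=37.75,
        weight_mean_kg=68.00,
        weight_sd_kg=13.30,
        height_mean_m=1.62,
        height_sd_m=0.05,
        site_means_mm=means,
        site_sds_mm=sds,
        seed=seed,
    )
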