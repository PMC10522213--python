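"""Inter- and intra-observer reliability of triplicate skinfold measurements.

The measurement design: observer A measures each site three times (pass A1),
observer B measures the same sites in triplicate (pass B), then observer A
repeats (pass A2), all on the same day.  Agreement of A1 with B across
subjects is inter-observer reliability (reproducibility); agreement of A1
with A2 is intra-observer reliability (repeatability).  Each comparison is
quantified with Lin's concordance correlation coefficient on the per-pass
triplicate means, both for the raw sites and propagated through the
three-site skinfold sum, body density and Siri percent fat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .agreement import AgreementEstimate, AgreementError, PairedSample, lin_ccc
from .anthro import (
    DomainError,
    MissingSiteError,
    Protocol,
    SkinfoldProfile,
    density_jpw,
    siri_percent_fat,
    sum_skinfolds,
)

logger = logging.getLogger(__name__)

PASSES = ("A1", "B", "A2")

#: Sites required for the reliability chain (the three-site density equation).
RELIABILITY_SITES = ("triceps", "suprailiac", "medial_thigh")

#: Quantities reported, in table order.
QUANTITIES = ("triceps", "suprailiac", "medial_thigh", "sum_sf", "percent_bf")

COMPARISONS = {"inter": ("A1", "B"), "intra": ("A1", "A2")}


class SessionError(ValueError):
    """Malformed or incomplete observer-session data."""


@dataclass(frozen=True)
class ObserverSession:
    """Triplicate skinfold readings for one subject and one observer pass.

    ``readings`` maps site name -> tuple of exactly three positive mm values.
    Sites beyond the three required ones are carried through untouched.
    """

    subject_id: str
    observer_pass: str
    readings: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.observer_pass not in PASSES:
            raise SessionError(
                f"observer_pass must be one of {PASSES}, got {self.observer_pass!r}"
            )
        for site, triple in self.readings.items():
            if len(triple) != 3:
                raise SessionError(
                    f"site {site!r} of subject {self.subject_id!r} has "
                    f"{len(triple)} readings, expected 3"
                )
            if any(not (v > 0 and np.isfinite(v)) for v in triple):
                raise SessionError(
                    f"non-positive reading at site {site!r} of subject {self.subject_id!r}"
                )

    def site_mean(self, site: str) -> float:
        if site not in self.readings:
            raise MissingSiteError(
                f"subject {self.subject_id!r} pass {self.observer_pass} missing site {site!r}"
            )
        return average_triplicate(self.readings[site])


@dataclass(frozen=True)
class ReliabilityReport:
    """Lin CCCs keyed by (quantity, comparison), plus bookkeeping counts."""

    estimates: Mapping[tuple[str, str], AgreementEstimate]
    n_subjects: int
    n_dropped: int
    dropped_ids: tuple[str, ...] = field(default=())


def average_triplicate(triple: Iterable[float]) -> float:
    """Arithmetic mean of exactly three positive readings (mm)."""
    vals = [float(v) for v in triple]
    if len(vals) != 3:
        raise SessionError(f"expected exactly 3 readings, got {len(vals)}")
    if any(not (v > 0 and np.isfinite(v)) for v in vals):
        raise SessionError(f"readings must be positive and finite, got {vals}")
    return sum(vals) / 3.0


def session_derivatives(session: ObserverSession, age_years: float) -> tuple[float, float, float]:
    """(sum3_mm, density, percent_bf) chained from one session's site means.

    Site triplicate means feed the three-site sum, then the three-site density
    equation, then the Siri conversion.
    """
    means = {s: session.site_mean(s) for s in RELIABILITY_SITES}
    profile = SkinfoldProfile(
        subject_id=session.subject_id,
        triceps_mm=means["triceps"],
        suprailiac_mm=means["suprailiac"],
        medial_thigh_mm=means["medial_thigh"],
    )
    s3 = sum_skinfolds(profile, Protocol.JPW)
    dens = density_jpw(s3, age_years)
    pbf = siri_percent_fat(dens)
    return s3, dens.value, pbf.value


def reliability_analysis(
    sessions: Iterable[ObserverSession],
    ages: Mapping[str, float],
    alpha: float = 0.05,
) -> ReliabilityReport:
    """Inter- (A1 vs B) and intra-observer (A1 vs A2) CCCs across subjects.

    Subjects missing any of the three passes, a required site, or an age are
    dropped (counted and logged); at least three complete subjects must
    remain.  For each retained subject the per-pass quantities are the three
    site means plus the derived skinfold sum and percent fat.
    """
    by_subject: dict[str, dict[str, ObserverSession]] = {}
    for s in sessions:
        slot = by_subject.setdefault(s.subject_id, {})
        if s.observer_pass in slot:
            raise SessionError(
                f"duplicate pass {s.observer_pass} for subject {s.subject_id!r}"
            )
        slot[s.observer_pass] = s

    complete: list[str] = []
    dropped: list[str] = []
    values: dict[tuple[str, str], list[float]] = {
        (q, p): [] for q in QUANTITIES for p in PASSES
    }
    for sid in sorted(by_subject):
        passes = by_subject[sid]
        if set(PASSES) - set(passes) or sid not in ages:
            dropped.append(sid)
            continue
        try:
            per_pass = {}
            for p in PASSES:
                s3, _, pbf = session_derivatives(passes[p], ages[sid])
                per_pass[p] = {
                    **{site: passes[p].site_mean(site) for site in RELIABILITY_SITES},
                    "sum_sf": s3,
                    "percent_bf": pbf,
                }
        except (MissingSiteError, DomainError) as exc:
            logger.warning("dropping subject %s: %s", sid, exc)
            dropped.append(sid)
            continue
        complete.append(sid)
        for q in QUANTITIES:
            for p in PASSES:
                values[(q, p)].append(per_pass[p][q])

    if dropped:
        logger.warning("reliability analysis dropped %d incomplete subject(s)", len(dropped))
    if len(complete) < 3:
        raise AgreementError(
            f"need >= 3 complete subjects for reliability analysis, got {len(complete)}"
        )

    estimates: dict[tuple[str, str], AgreementEstimate] = {}
    for q in QUANTITIES:
        for comp, (pa, pb) in COMPARISONS.items():
            sample = PairedSample(
                np.array(values[(q, pa)]), np.array(values[(q, pb)]), labels=(pa, pb)
            )
            estimates[(q, comp)] = lin_ccc(sample, alpha=alpha)
    return ReliabilityReport(
        estimates=estimates,
        n_subjects=len(complete),
        n_dropped=len(dropped),
        dropped_ids=tuple(dropped),
    )
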