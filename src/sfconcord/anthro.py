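"""Skinfold anthropometry: sums, body-density prediction and the Siri conversion.

Two sex-specific body-density equations for adult women are implemented:

* a three-site quadratic in the sum of triceps, suprailiac and medial-thigh
  skinfolds with a linear age term (Jackson, Pollock & Ward 1980 protocol,
  ``JPW``), and
* a four-site log10 equation in the sum of average-axillary, suprailiac,
  medial-thigh and medial-calf skinfolds (Petroski 1995 protocol, ``PET``).

Density (g/cm^3 scale, dimensionless here) is converted to percent body fat
with the two-compartment Siri equation ``%BF = 495/D - 450``.

All arithmetic is carried in full double precision; rounding happens only at
report time.  Negative percent fat is returned as computed (and can be flagged
by validation) rather than clipped, because clipping would bias downstream
agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Protocol(str, Enum):
    """Skinfold protocol selecting which sites enter the density equation."""

    JPW = "JPW"
    PET = "PET"


class Method(str, Enum):
    """Body-fat estimation method labels used throughout the pipeline."""

    SF_JPW = "SF_JPW"
    SF_PET = "SF_PET"
    BIA = "BIA"
    DXA = "DXA"


#: Canonical site keys, in measurement-sheet order.
SITES = (
    "triceps",
    "subscapular",
    "suprailiac",
    "average_axillary",
    "medial_thigh",
    "medial_calf",
)

#: Sites required by each protocol, in summation order.
PROTOCOL_SITES = {
    Protocol.JPW: ("triceps", "suprailiac", "medial_thigh"),
    Protocol.PET: ("average_axillary", "suprailiac", "medial_thigh", "medial_calf"),
}

MAX_SKINFOLD_MM = 100.0  # validation bound: beyond caliper range


class DomainError(ValueError):
    """An input outside the mathematical or physiological domain of an operation."""


class MissingSiteError(DomainError):
    """A skinfold site required by the selected protocol is absent."""


@dataclass(frozen=True)
class SkinfoldProfile:
    """Six-site skinfold record for one subject, all values in millimetres.

    The subscapular site is carried for completeness of the measurement
    record although neither implemented equation uses it; it may be None.
    Any site may be None (missing); present values must lie in (0, 100] mm.
    """

    subject_id: str
    triceps_mm: Optional[float] = None
    subscapular_mm: Optional[float] = None
    suprailiac_mm: Optional[float] = None
    average_axillary_mm: Optional[float] = None
    medial_thigh_mm: Optional[float] = None
    medial_calf_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for site in SITES:
            v = getattr(self, f"{site}_mm")
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0 or v > MAX_SKINFOLD_MM:
                raise DomainError(
                    f"skinfold {site!r} = {v} mm outside (0, {MAX_SKINFOLD_MM}] "
                    f"for subject {self.subject_id!r}"
                )

    def site(self, name: str) -> float:
        """Return the measurement at *name*, raising if missing."""
        v = getattr(self, f"{name}_mm")
        if v is None:
            raise MissingSiteError(
                f"subject {self.subject_id!r} is missing required site {name!r}"
            )
        return float(v)


@dataclass(frozen=True)
class Subject:
    """Demographics and body size for one subject; BMI is derived on construction."""

    subject_id: str
    age_years: float
    weight_kg: float
    height_m: float
    bmi_kg_m2: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.age_years > 0 and math.isfinite(self.age_years)):
            raise DomainError(f"age must be positive, got {self.age_years}")
        if not (self.weight_kg > 0 and math.isfinite(self.weight_kg)):
            raise DomainError(f"weight must be positive, got {self.weight_kg}")
        if not (1.0 < self.height_m < 2.5):
            raise DomainError(f"height {self.height_m} m outside (1.0, 2.5)")
        object.__setattr__(self, "bmi_kg_m2", bmi(self.weight_kg, self.height_m))

    def validation_warnings(self) -> list[str]:
        """Soft range checks (study window 18-37 y, BMI 18-39.9); warn, not reject."""
        w = []
        if not (10 < self.age_years < 90):
            w.append(f"age {self.age_years} outside plausible (10, 90)")
        elif not (18 <= self.age_years <= 37):
            w.append(f"age {self.age_years} outside study window [18, 37]")
        if not (18 <= self.bmi_kg_m2 <= 39.9):
            w.append(f"BMI {self.bmi_kg_m2:.2f} outside study window [18, 39.9]")
        return w


@dataclass(frozen=True)
class BodyDensity:
    """A predicted body density with the protocol that produced it."""

    value: float
    protocol: Protocol

    def __post_init__(self) -> None:
        if not (0.90 < self.value < 1.20):
            raise DomainError(
                f"body density {self.value:.6f} outside sanity bound (0.90, 1.20)"
            )


@dataclass(frozen=True)
class PercentBodyFat:
    """A percent-body-fat value with the estimating method.

    Values outside a wide sanity band are rejected; negative values within the
    band are legal (very lean inputs can produce them) and are surfaced via
    :meth:`flags` rather than clipped.
    """

    value: float
    method: Method

    def __post_init__(self) -> None:
        if not (-10.0 < self.value < 80.0):
            raise DomainError(
                f"%BF {self.value:.3f} outside sanity bound (-10, 80) for {self.method}"
            )

    def flags(self) -> list[str]:
        return [f"negative %BF {self.value:.3f} ({self.method.value})"] if self.value < 0 else []


def sum_skinfolds(profile: SkinfoldProfile, protocol: Protocol) -> float:
    """Sum of the skinfold sites required by *protocol*, in mm.

    JPW: triceps + suprailiac + medial thigh.
    PET: average axillary + suprailiac + medial thigh + medial calf.

    Raises :class:`MissingSiteError` naming the first absent required site.
    """
    protocol = Protocol(protocol)
    return float(sum(profile.site(s) for s in PROTOCOL_SITES[protocol]))


def density_jpw(sum3_mm: float, age_years: float) -> BodyDensity:
    """Three-site body density: quadratic in the skinfold sum, linear in age.

    D = 1.0994921 - 0.0009929*S + 0.0000023*S^2 - 0.0001392*age,
    with S = triceps + suprailiac + medial thigh (mm).

    The quadratic's vertex sits at S ≈ 215.85 mm; the equation is decreasing
    in S below that, which covers the measurable range.
    """
    if sum3_mm < 0 or not math.isfinite(sum3_mm):
        raise DomainError(f"sum of 3 skinfolds must be >= 0 mm, got {sum3_mm}")
    if age_years < 0 or not math.isfinite(age_years):
        raise DomainError(f"age must be >= 0 years, got {age_years}")
    d = (
        1.0994921
        - 0.0009929 * sum3_mm
        + 0.0000023 * sum3_mm * sum3_mm
        - 0.0001392 * age_years
    )
    return BodyDensity(d, Protocol.JPW)


def density_pet(sum4_mm: float, age_years: float) -> BodyDensity:
    """Four-site body density: log10 of the skinfold sum, linear in age.

    D = 1.19547130 - 0.07513507*log10(S) - 0.00041072*age,
    with S = average axillary + suprailiac + medial thigh + medial calf (mm).
    """
    if sum4_mm <= 0 or not math.isfinite(sum4_mm):
        raise DomainError(f"sum of 4 skinfolds must be > 0 mm (log10 domain), got {sum4_mm}")
    if age_years < 0 or not math.isfinite(age_years):
        raise DomainError(f"age must be >= 0 years, got {age_years}")
    d = 1.19547130 - 0.07513507 * math.log10(sum4_mm) - 0.00041072 * age_years
    return BodyDensity(d, Protocol.PET)


#: Density protocol -> percent-fat method label.
_PROTOCOL_METHOD = {Protocol.JPW: Method.SF_JPW, Protocol.PET: Method.SF_PET}


def siri_percent_fat(density: BodyDensity) -> PercentBodyFat:
    """Two-compartment Siri conversion, %BF = 495/D - 450.

    Strictly decreasing in density; D = 1.1 maps to exactly 0 %BF.
    """
    if density.value <= 0:
        raise DomainError(f"density must be positive, got {density.value}")
    return PercentBodyFat(495.0 / density.value - 450.0, _PROTOCOL_METHOD[density.protocol])


def percent_fat_from_profile(
    profile: SkinfoldProfile, age_years: float, protocol: Protocol
) -> PercentBodyFat:
    """Convenience chain: site sum -> density -> Siri %BF for one protocol."""
    protocol = Protocol(protocol)
    s = sum_skinfolds(profile, protocol)
    dens = density_jpw(s, age_years) if protocol is Protocol.JPW else density_pet(s, age_years)
    return siri_percent_fat(dens)


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError(f"weight and height must be positive, got {weight_kg}, {height_m}")
    return weight_kg / (height_m * height_m)
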