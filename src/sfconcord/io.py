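"""CSV schemas, validated loading and report emission.

Two input schemas (UTF-8, comma-separated, header row, dot decimal, missing
values as empty cells):

subjects.csv — one row per subject:
    subject_id, age_years, weight_kg, height_m,
    tsf_mm, ssf_mm, sisf_mm, aasf_mm, mtsf_mm, csf_mm, bia_pbf, dxa_pbf

sessions.csv — long format, one row per site per observer pass:
    subject_id, observer_pass (A1|B|A2), site, reading1_mm, reading2_mm, reading3_mm

Rows that violate a range or miss a required value are excluded from analysis
and reported in the issue log with their row number; malformed headers are
fatal.  Loading never silently drops data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .anthro import DomainError, SkinfoldProfile, Subject
from .reliability import ObserverSession, SessionError

logger = logging.getLogger(__name__)

SUBJECT_COLUMNS = [
    "subject_id",
    "age_years",
    "weight_kg",
    "height_m",
    "tsf_mm",
    "ssf_mm",
    "sisf_mm",
    "aasf_mm",
    "mtsf_mm",
    "csf_mm",
    "bia_pbf",
    "dxa_pbf",
]

SESSION_COLUMNS = [
    "subject_id",
    "observer_pass",
    "site",
    "reading1_mm",
    "reading2_mm",
    "reading3_mm",
]

#: column name -> SkinfoldProfile site keyword
_SITE_COLS = {
    "tsf_mm": "triceps_mm",
    "ssf_mm": "subscapular_mm",
    "sisf_mm": "suprailiac_mm",
    "aasf_mm": "average_axillary_mm",
    "mtsf_mm": "medial_thigh_mm",
    "csf_mm": "medial_calf_mm",
}

#: long-format site labels accepted in sessions.csv
SESSION_SITES = ("triceps", "suprailiac", "medial_thigh")


class SchemaError(ValueError):
    """Fatal structural problem with an input file (bad header, empty file)."""


@dataclass(frozen=True)
class Issue:
    """One data problem: the input row it came from and what happened to it."""

    row: int  # 1-based data row number (header excluded)
    subject_id: str
    message: str
    excluded: bool


@dataclass(frozen=True)
class SubjectRecord:
    """A validated subject row: demographics, skinfolds and the two device %BF."""

    subject: Subject
    profile: SkinfoldProfile
    bia_pbf: Optional[float]
    dxa_pbf: Optional[float]


def _check_header(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: header missing required column(s) {missing}")
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: file contains no data rows")


def load_subjects(path: str | Path) -> tuple[list[SubjectRecord], list[Issue]]:
    """Read and validate a subjects.csv; returns complete records plus issues."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _check_header(df, SUBJECT_COLUMNS, path)
    records: list[SubjectRecord] = []
    issues: list[Issue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.subject_id)
        try:
            subj = Subject(sid, float(row.age_years), float(row.weight_kg), float(row.height_m))
            site_kwargs = {
                _SITE_COLS[c]: (None if pd.isna(getattr(row, c)) else float(getattr(row, c)))
                for c in _SITE_COLS
            }
            prof = SkinfoldProfile(subject_id=sid, **site_kwargs)
        except (DomainError, ValueError, TypeError) as exc:
            issues.append(Issue(i, sid, f"excluded: {exc}", excluded=True))
            continue
        for w in subj.validation_warnings():
            issues.append(Issue(i, sid, f"warning: {w}", excluded=False))
        bia = None if pd.isna(row.bia_pbf) else float(row.bia_pbf)
        dxa = None if pd.isna(row.dxa_pbf) else float(row.dxa_pbf)
        records.append(SubjectRecord(subj, prof, bia, dxa))
    for issue in issues:
        (logger.warning if issue.excluded else logger.info)(
            "row %d (%s): %s", issue.row, issue.subject_id, issue.message
        )
    return records, issues


def load_sessions(path: str | Path) -> tuple[list[ObserverSession], list[Issue]]:
    """Read a long-format sessions.csv into per-pass ObserverSession objects.

    Rows are grouped by (subject, pass); a bad reading excludes that entire
    pass (a partial pass cannot feed the density chain) and is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "observer_pass": str, "site": str})
    _check_header(df, SESSION_COLUMNS, path)
    issues: list[Issue] = []
    grouped: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = {}
    bad_pass: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        key = (str(row.subject_id), str(row.observer_pass))
        try:
            triple = (float(row.reading1_mm), float(row.reading2_mm), float(row.reading3_mm))
            if any(not (v > 0) for v in triple):
                raise ValueError(f"non-positive reading {triple}")
        except (ValueError, TypeError) as exc:
            issues.append(Issue(i, key[0], f"pass {key[1]} excluded: {exc}", excluded=True))
            bad_pass.add(key)
            continue
        grouped.setdefault(key, {})[str(row.site)] = triple
    sessions: list[ObserverSession] = []
    for (sid, pass_name), readings in grouped.items():
        if (sid, pass_name) in bad_pass:
            continue
        try:
            sessions.append(ObserverSession(sid, pass_name, readings))
        except SessionError as exc:
            issues.append(Issue(-1, sid, f"pass {pass_name} excluded: {exc}", excluded=True))
    for issue in issues:
        logger.warning("row %d (%s): %s", issue.row, issue.subject_id, issue.message)
    return sessions, issues


# ---------------------------------------------------------------------------
# writers


def subjects_frame(cohort) -> pd.DataFrame:
    """Synthetic cohort -> subjects.csv schema DataFrame."""
    rows = []
    for subj, prof, panel in zip(cohort.subjects, cohort.profiles, cohort.panels):
        rows.append(
            {
                "subject_id": subj.subject_id,
                "age_years": subj.age_years,
                "weight_kg": subj.weight_kg,
                "height_m": subj.height_m,
                "tsf_mm": prof.triceps_mm,
                "ssf_mm": prof.subscapular_mm,
                "sisf_mm": prof.suprailiac_mm,
                "aasf_mm": prof.average_axillary_mm,
                "mtsf_mm": prof.medial_thigh_mm,
                "csf_mm": prof.medial_calf_mm,
                "bia_pbf": panel.bia,
                "dxa_pbf": panel.dxa,
            }
        )
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def sessions_frame(sessions: list[ObserverSession]) -> pd.DataFrame:
    """Observer sessions -> long-format sessions.csv schema DataFrame."""
    rows = []
    for s in sessions:
        for site, triple in s.readings.items():
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "observer_pass": s.observer_pass,
                    "site": site,
                    "reading1_mm": triple[0],
                    "reading2_mm": triple[1],
                    "reading3_mm": triple[2],
                }
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_manifest(path: str | Path, **fields) -> Path:
    """Structured-text run manifest (YAML): seed, config echo, counts, version."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"sfconcord_version": __version__, **fields}
    path.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    return path
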