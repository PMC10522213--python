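"""Shared fixtures: small seeded synthetic inputs, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from sfconcord import io as sfio
from sfconcord import simulate


@pytest.fixture(scope="session")
def cohort():
    """Calibrated inter-method cohort (n=90), fixed seed."""
    return simulate.generate_cohort(simulate.CohortConfig(seed=12345))


@pytest.fixture(scope="session")
def cohort_records(cohort):
    return [
        sfio.SubjectRecord(s, p, panel.bia, panel.dxa)
        for s, p, panel in zip(cohort.subjects, cohort.profiles, cohort.panels)
    ]


@pytest.fixture(scope="session")
def reliability_cohort():
    """Calibrated observer-reliability cohort (n=59), fixed seed."""
    return simulate.generate_cohort(simulate.reliability_cohort_config(seed=54321))


@pytest.fixture(scope="session")
def observer_sessions(reliability_cohort):
    return simulate.generate_observer_sessions(
        reliability_cohort.profiles, simulate.ObserverErrorConfig(seed=99)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
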