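"""Shared fixtures: fast generator configs and cached synthetic cohorts."""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fmtheta as fm
from fmtheta.config import SEGMENT_LABELS
from fmtheta.feedback import BaselineReference, SessionRecord

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def fast_config() -> fm.GeneratorConfig:
    """Generator with shortened segments for cheap per-test simulations."""
    return fm.GeneratorConfig(segment_duration_s=10.0)


def make_sessions(amp: np.ndarray) -> list[SessionRecord]:
    """Build 8 session records straight from an 8x8 amplitude matrix."""
    amp = np.asarray(amp, dtype=float)
    assert amp.shape == (8, 8)
    return [
        SessionRecord(
            session_index=s + 1, segment_labels=SEGMENT_LABELS,
            segment_amp_uv=amp[s].copy(),
            n_windows_used=np.full(8, 100), n_windows_rejected=np.zeros(8, int),
            baseline_reference=BaselineReference(amp[s, 0], amp[s, 0] * 0.5,
                                                 amp[s, 0] * 1.5 + 1e-9),
        )
        for s in range(8)
    ]


@pytest.fixture()
def session_factory():
    return make_sessions


def _run_cohort(n_subjects: int, seed: int) -> fm.StudyResult:
    config = fm.StudyConfig(
        generator=fm.GeneratorConfig(segment_duration_s=20.0, n_subjects=n_subjects),
        seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fm.run_study(config)


@pytest.fixture(scope="session")
def cohort40() -> fm.StudyResult:
    """Default 40-subject cohort through the full pipeline (20-s segments)."""
    return _run_cohort(40, seed=3)


@pytest.fixture(scope="session")
def cohort200() -> fm.StudyResult:
    """Parameter-recovery cohort for the stepwise regressions."""
    return _run_cohort(200, seed=1)
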