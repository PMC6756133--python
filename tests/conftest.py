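"""Shared fixtures.

The expensive end-to-end study (synthetic generation + full pipeline) is
session-scoped so the pipeline tests and the end-to-end acceptance checks
share a single run.  Problem sizes here are the deliberate desk-scale
study conditions: 8 subjects, SNRs from -12.5 dB to +2.5 dB plus quiet,
two presentations per stimulus, 240 s training stories.
"""

import numpy as np
import pytest

from envtrack.pipeline import AnalysisConfig, run_study
from envtrack.synthetic import SyntheticStudyConfig, gen_study

STUDY_CONFIG = SyntheticStudyConfig(
    n_subjects=8,
    snr_grid=(-12.5, -9.5, -6.5, -3.5, 2.5, None),
    repetitions=2,
    story_duration_s=240.0,
    seed=20,
)

ANALYSIS_CONFIG = AnalysisConfig(
    lags_ms=(0.0, 75.0),
    n_boot=100,
    n_perm=1000,
    n_boot_psychometric=30,
    seed=20,
)


@pytest.fixture(scope="session")
def study_report():
    """Full analysis of the default-scale synthetic study (runs once)."""
    return run_study(gen_study(STUDY_CONFIG), ANALYSIS_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
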