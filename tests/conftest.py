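"""Shared fixtures: small deterministic cohorts at both generator tiers."""

from __future__ import annotations

import numpy as np
import pytest

from docentropy.pipeline import run_full_analysis
from docentropy.simulate import CohortConfig, generate_cohort


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def feature_cohort():
    """Full-size (162-subject) cohort at the fast feature tier."""
    return generate_cohort(CohortConfig(seed=3), signals=False)


@pytest.fixture(scope="session")
def small_signal_result():
    """End-to-end pipeline result on a small signal-tier cohort.

    10 + 10 subjects with 4,096-sample epochs keeps the entropy stage to a
    few seconds while exercising every stage on measured (not proxy)
    entropy values.
    """
    cfg = CohortConfig(n_uws=10, n_mcs=10, epoch_len=4096, seed=11)
    return run_full_analysis(cfg, signals=True)
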