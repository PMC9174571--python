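"""Shared fixtures: small simulated cohorts processed once per session."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from epibeat.pipeline import PipelineConfig, simulate_and_extract
from epibeat.simulate import (PacingConfig, default_subjects,
                              simulate_dataset)

logging.getLogger("epibeat").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """Desk-scale study: 2 subjects, 10 s per pacing setting."""
    return PipelineConfig(
        seed=42,
        n_subjects=2,
        duration_s=10.0,
        locations=("mitral_valve",),
        artifact_rate=0.05,
        k=4,
        search_k=3,
        search_n_trees=8,
        n_trees=20,
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    """Feature/target table from the full chain on the small study."""
    table, drop_log, qc = simulate_and_extract(small_config)
    return table, drop_log, qc


@pytest.fixture(scope="session")
def one_recording():
    """A single 12 s recording with ground truth and no artifacts."""
    subjects = default_subjects(1, seed=7, locations=("mitral_valve",))
    cfg = PacingConfig("BiV", 150, 0, "baseline", duration_s=12.0)
    recs, truths = simulate_dataset(
        subjects, [cfg], ("mitral_valve",), artifact_rate=0.0, seed=7)
    return recs[0], truths[0], cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
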