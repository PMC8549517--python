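"""Shared fixtures: simulated datasets and pipeline runs reused across tests.

Session-scoped fixtures hold the expensive end-to-end runs (simulation,
realignment, full pipeline) so each is executed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from bravointegrate.pipeline import PipelineConfig, run_pipeline
from bravointegrate.synthdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small error-free experiment: 6 HIM segments, 24 integrations."""
    return SimConfig(
        host_length=80_000,
        wasp_length=40_000,
        n_segments=6,
        n_integrations_total=24,
        depth_host=25,
        depth_wasp=25,
        error_rate=0.0,
        pcr_dup_rate=0.02,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    """Full pipeline run on the small error-free experiment."""
    return run_pipeline(PipelineConfig(sim=small_config, seed=101, null_reads=2_000))


@pytest.fixture(scope="session")
def study_result():
    """The reference study conditions: 16 HIM segments, 200 integrations,
    microhomologies 0-5 bp, no sequencing errors, 30x depth on both genomes."""
    config = SimConfig(
        host_length=300_000,
        wasp_length=60_000,
        n_segments=16,
        n_integrations_total=200,
        depth_host=30,
        depth_wasp=30,
        error_rate=0.0,
        pcr_dup_rate=0.02,
        seed=42,
    )
    return run_pipeline(PipelineConfig(sim=config, seed=42, null_reads=2_000))


@pytest.fixture(scope="session")
def study_result_with_errors():
    """Same study conditions with a 0.1% per-base substitution error rate."""
    config = SimConfig(
        host_length=300_000,
        wasp_length=60_000,
        n_segments=16,
        n_integrations_total=200,
        depth_host=30,
        depth_wasp=30,
        error_rate=0.001,
        pcr_dup_rate=0.02,
        seed=42,
    )
    return run_pipeline(PipelineConfig(sim=config, seed=42, null_reads=2_000))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
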