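"""Shared fixtures: one moderately sized synthetic experiment per session."""

from __future__ import annotations

import pytest

from hifmeth.pipeline import PipelineConfig, run_pipeline
from hifmeth.simulate import (
    SimulationConfig,
    plant_truth,
    simulate_cohort,
    simulate_expression,
    simulate_marker_tracks,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_genes=800, n_probes=1500, seed=3)


@pytest.fixture(scope="session")
def truth(sim_config):
    return plant_truth(sim_config)


@pytest.fixture(scope="session")
def expression(sim_config, truth):
    return simulate_expression(sim_config, truth)


@pytest.fixture(scope="session")
def beta_and_manifest(sim_config, truth):
    return simulate_methylation(sim_config, truth)


@pytest.fixture(scope="session")
def beta(beta_and_manifest):
    return beta_and_manifest[0]


@pytest.fixture(scope="session")
def manifest(beta_and_manifest):
    return beta_and_manifest[1]


@pytest.fixture(scope="session")
def tracks(sim_config, truth):
    return simulate_marker_tracks(sim_config, truth)


@pytest.fixture(scope="session")
def cohort(sim_config, truth):
    return simulate_cohort(sim_config, truth)


@pytest.fixture(scope="session")
def bundle(sim_config, expression, beta, manifest, truth, tracks, cohort):
    """Full pipeline run on the session's synthetic experiment."""
    config = PipelineConfig(seed=sim_config.seed, n_perm=2000)
    return run_pipeline(
        config,
        expression=expression,
        beta=beta,
        manifest=manifest,
        gene_coords=truth.gene_coords,
        tracks=tracks,
        cohort=cohort,
    )
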