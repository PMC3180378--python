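"""Shared fixtures: one small simulated study reused across test modules."""

import pytest

from srnakit.pipeline import run_pipeline
from srnakit.simdata import SampleSpec, SimulationConfig


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def samples():
    return [
        SampleSpec("pESC1", "female", "one_active_X"),
        SampleSpec("pESC2", "female", "two_active_X"),
        SampleSpec("ivfM", "male", "male"),
    ]


@pytest.fixture(scope="session")
def study(config, samples):
    """Full pipeline run over the default study conditions."""
    return run_pipeline(config, samples)


@pytest.fixture(scope="session")
def genome(study):
    return study.genome
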