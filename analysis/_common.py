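"""Shared study definition for the numbered analysis scripts.

Four simulated cell lines mirror the study design: two test lines of
unknown X status (one of which truly carries two active X chromosomes),
one female reference line with known one-active-X status and one male
reference line.  All scripts derive their inputs from this single
deterministic configuration, so each one can be run standalone.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from srnakit.pipeline import PipelineResult, run_pipeline
from srnakit.simdata import SampleSpec, SimulationConfig

SEED = 2011

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SAMPLES = [
    SampleSpec("pESC1", "female", "one_active_X"),
    SampleSpec("pESC2", "female", "two_active_X"),
    SampleSpec("ivfF", "female", "one_active_X"),
    SampleSpec("ivfM", "male", "male"),
]

#: reference pool for the X-inactivation caller: the male line plus the
#: female line of known one-active-X status
REFERENCE_SAMPLES = ["ivfM", "ivfF"]
TEST_SAMPLES = ["pESC1", "pESC2"]


def config() -> SimulationConfig:
    return SimulationConfig(seed=SEED)


@lru_cache(maxsize=1)
def study() -> PipelineResult:
    RESULTS.mkdir(exist_ok=True)
    return run_pipeline(config(), SAMPLES)
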