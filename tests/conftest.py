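"""Shared fixtures: one reduced synthetic survey and one fitted pipeline run.

Session scope keeps the suite fast: most tests interrogate the same survey
realisation rather than regenerating data.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sbtindex import RunConfig, SimConfig, run
from sbtindex.simulate import simulate_survey

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_config() -> SimConfig:
    return SimConfig.reduced(seed=11)


@pytest.fixture(scope="session")
def sim(reduced_config):
    """One reduced synthetic survey (6 years x 3 months x 5 areas)."""
    return simulate_survey(reduced_config, rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def pipeline_result(reduced_config):
    """Full pipeline run on the reduced survey, shared across tests."""
    return run(RunConfig(simulate=reduced_config, seed=11))
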