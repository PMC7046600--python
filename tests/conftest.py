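"""Shared fixtures: synthetic sessions at the study's conditions.

Heavy fixtures are session-scoped so the 20-minute sessions are
generated once and shared between the recovery and significance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from steptheta.config import PipelineConfig
from steptheta.synth import SynthSessionConfig, generate_session


@pytest.fixture(scope="session")
def pcfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def nine_sessions():
    """Nine 20-min sessions (3 animals x 3 sessions) with step-trough
    theta coupling injected at resultant 0.10, 226 degrees."""
    return [generate_session(SynthSessionConfig(seed=i))
            for i in range(1, 10)]


@pytest.fixture(scope="session")
def short_session():
    """One 3-min default-condition session for smoke tests."""
    return generate_session(SynthSessionConfig(duration_s=180.0, seed=3))


@pytest.fixture(scope="session")
def medium_session():
    """A 400-s session: ~2000 troughs, enough for stable phase stats."""
    return generate_session(SynthSessionConfig(duration_s=400.0, seed=21))


def make_session(duration_s=120.0, seed=0, **kw):
    return generate_session(
        SynthSessionConfig(duration_s=duration_s, seed=seed, **kw))


@pytest.fixture()
def rng():
    # fresh, identically seeded stream per test: results do not depend
    # on test execution order
    return np.random.default_rng(12345)
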