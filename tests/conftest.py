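"""Shared fixtures: small, fast configurations for machinery tests.

The full-scale study conditions (N = 1000, long epochs) are exercised
only in the acceptance tests; everything else runs on scaled-down
systems that keep the same structure.
"""

import numpy as np
import pytest

from phasegate import EnsembleParams, TrialConfig


@pytest.fixture(scope="session")
def small_config():
    """A trial config small enough for second-scale closed-loop tests."""
    return TrialConfig(
        ensemble=EnsembleParams(N=100),
        M=100,
        baseline_duration=1200.0,
        post_duration=800.0,
        post_transient=200.0,
        learning_max_blocks=30,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
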