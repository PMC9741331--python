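"""Shared fixtures: deterministic synthetic tachograms and hand-built states."""

from collections import deque

import numpy as np
import pytest

from rriclean import Criteria, RRISequence, generate_clean_rri
from rriclean.cleaner import BACKUP_LENGTH, WINDOW_LENGTH, CleanerState


@pytest.fixture(scope="session")
def clean_seq():
    """A 20,000-beat artifact-free tachogram (mean 900 ms)."""
    return generate_clean_rri(20000, mean_ms=900.0, sd_ms=50.0, seed=1)


@pytest.fixture(scope="session")
def small_clean_seq():
    """A 3,000-beat artifact-free tachogram for cheaper tests."""
    return generate_clean_rri(3000, mean_ms=900.0, sd_ms=50.0, seed=2)


@pytest.fixture()
def bounded_seq():
    """Uniform-noise tachogram whose ratios can never leave 3-SD limits.

    Uniform noise is bounded at ~1.7 residual SDs, so a cleaning pass must
    classify every value normal — the exact-passthrough reference input.
    """
    rng = np.random.default_rng(7)
    return RRISequence(800.0 + rng.uniform(-40.0, 40.0, size=3000))


@pytest.fixture()
def steady_state():
    """Factory for a cleaner state with a steady 800-ms rhythm.

    Window and backup field are all 800 ms, criteria (0.82, 1.18) — the
    configuration the worked fill/merge arithmetic examples assume.
    """

    def make(buffer_ms: float = 0.0, seed: int = 0) -> CleanerState:
        return CleanerState(
            moving_window=deque([800.0] * WINDOW_LENGTH, maxlen=WINDOW_LENGTH),
            backup_field=deque([800.0] * BACKUP_LENGTH, maxlen=BACKUP_LENGTH),
            criteria=Criteria(residual_sd=0.06, multiplier=3.0),
            buffer_ms=buffer_ms,
            rng=np.random.default_rng(seed),
        )

    return make
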