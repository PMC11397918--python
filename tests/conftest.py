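"""Shared fixtures: small simulated frames and helper factories.

All fixtures are generated programmatically; heavier session-scoped ones
are cached so several test modules can reuse the same frames.
"""

import numpy as np
import pytest

from rfpipe import sim


@pytest.fixture(scope="session")
def acq():
    return sim.AcquisitionSpec()


@pytest.fixture(scope="session")
def small_acq():
    """Full axial depth but few lines: fast to simulate, still gate-eligible."""
    return sim.AcquisitionSpec(n_lines=16)


@pytest.fixture(scope="session")
def frame(acq):
    return sim.simulate_frame(sim.PhantomSpec(stage=2), acq, seed=42,
                              frame_id="fixture")


@pytest.fixture(scope="session")
def small_frames(small_acq):
    """Six labeled 1247 x 16 frames, stages 0 and 4 alternating."""
    out = []
    for i in range(6):
        stage = 0 if i % 2 == 0 else 4
        out.append(sim.simulate_frame(
            sim.PhantomSpec(stage=stage, effect_scale=2.0), small_acq,
            seed=100 + i, frame_id=f"sf{i}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
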