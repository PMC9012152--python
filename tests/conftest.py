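import numpy as np
import pytest

from pafscreen import PipelineConfig, RhythmSpec, gen_recording, gen_rr

#: Operating threshold used across behavioral tests; the value the
#: screen-level calibration selects under the default generator conditions.
CAL_THRESHOLD = 0.065


@pytest.fixture
def config():
    return PipelineConfig(threshold=CAL_THRESHOLD)


@pytest.fixture
def nsr_31():
    return gen_rr(RhythmSpec("NSR", 31, seed=1))


@pytest.fixture
def af_31():
    return gen_rr(RhythmSpec("AF", 31, seed=1))


@pytest.fixture
def bigeminy_31():
    return gen_rr(RhythmSpec("BIGEMINY", 31, seed=1))


@pytest.fixture
def trigeminy_31():
    return gen_rr(RhythmSpec("TRIGEMINY", 31, seed=1))


@pytest.fixture
def nsr_af_nsr_recording():
    episodes = [
        (RhythmSpec("NSR", 200), "N"),
        (RhythmSpec("AF", 150), "AFIB"),
        (RhythmSpec("NSR", 200), "N"),
    ]
    return gen_recording(episodes, seed=7)


def class_seeds(n, offset=0):
    """Deterministic per-segment seeds for corpus tests."""
    rng = np.random.default_rng(20_240_000 + offset)
    return rng.integers(0, 2**31 - 1, size=n)
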