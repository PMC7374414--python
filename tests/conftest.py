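import numpy as np
import pytest

from pcg_chd.synthetic_pcg import SynthParams, make_dataset

# all simulated-study fixtures run at a reduced sampling rate; every window
# constant in the pipeline is specified in ms, so nothing depends on 44.1 kHz
TEST_FS = 4000.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """9 recordings (3 per class) at reduced rate for fast end-to-end tests."""
    params = SynthParams(fs=TEST_FS, duration_s=5.0, snr_db=10.0)
    recs, manifest = make_dataset(3, params, seed=42)
    return recs, manifest


@pytest.fixture(scope="session")
def two_tone():
    """10 Hz + 100 Hz mixture, 1 s at 1 kHz — the canonical EMD separation case."""
    t = np.arange(1000) / 1000.0
    slow = np.sin(2 * np.pi * 10 * t)
    fast = 0.5 * np.sin(2 * np.pi * 100 * t)
    return slow + fast, slow, fast
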