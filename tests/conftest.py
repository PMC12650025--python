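import numpy as np
import pytest

from microfuse.records import EEGRecord
from microfuse import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ground_truth():
    """Control-group generating process: 19 channels, 4 states, SNR ~5."""
    return synth.default_control_ground_truth(seed=3)


@pytest.fixture(scope="session")
def noiseless_ground_truth():
    gt = synth.default_control_ground_truth(seed=3)
    return synth.MicrostateGroundTruth(
        templates=gt.templates,
        transition_matrix=gt.transition_matrix,
        mean_durations_ms=gt.mean_durations_ms,
        noise_sd=0.0,
        seed=gt.seed,
    )


@pytest.fixture(scope="session")
def noiseless_record(noiseless_ground_truth):
    """10 s noiseless synthetic record plus its generating labels."""
    gt = noiseless_ground_truth
    fs = 128.0
    n = int(10 * fs)
    labels = synth.simulate_state_sequence(gt, n, fs, seed=11)
    amps = synth.amplitude_series(n, fs, seed=12)
    rec = synth.synthesize_eeg(gt, labels, amps, seed=13, fs_hz=fs)
    return rec, labels


def make_record(data: np.ndarray, fs: float = 128.0, **kw) -> EEGRecord:
    return EEGRecord(data=np.asarray(data, dtype=float), fs_hz=fs, **kw)
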