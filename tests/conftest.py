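import numpy as np
import pytest

import microstates as m
from microstates.strategies import Dataset, extract_all_candidates


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects x 4 trials, 10 s at 250 Hz, SNR 5 — quick but structured."""
    cfg = m.SimulationConfig(
        n_subjects=4, n_trials_per_subject=4, trial_duration=10.0, snr=5.0, seed=7
    )
    sim = m.simulate_dataset(cfg)
    return sim


@pytest.fixture(scope="session")
def small_ds(small_dataset):
    return Dataset(small_dataset.recordings, small_dataset.manifest)


@pytest.fixture(scope="session")
def small_candidates(small_ds):
    return extract_all_candidates(small_ds)
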