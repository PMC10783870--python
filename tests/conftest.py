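import numpy as np
import pytest

from trfkit import BoostConfig, Kernel, TimeAxis, TimeSeries
from trfkit.simulate import SimSpec, ground_truth_kernel, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def axis100():
    """10 s at 100 Hz."""
    return TimeAxis(0.0, 0.01, 1000)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noiseless band-driven recording: response equals truth (*) predictors."""
    spec = SimSpec(duration=60.0, snr_db=np.inf, seed=3)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default study conditions: 8 correlated bands, pink noise at 0 dB, 60 s."""
    return simulate_dataset(SimSpec(seed=7))


def single_predictor_spec(seed: int, snr_db: float = -10.0) -> SimSpec:
    """Envelope-TRF-like design: one predictor, biphasic kernel, weak SNR."""
    kernel = ground_truth_kernel("biphasic", n_bands=1, n_channels=1)
    return SimSpec(
        duration=60.0, design="bands", n_bands=1, band_correlation=0.0,
        n_channels=1, kernel=kernel, snr_db=snr_db, seed=seed,
    )
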