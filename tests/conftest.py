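import numpy as np
import pytest

from erpbci import decoder as dec
from erpbci import paradigm as pg
from erpbci import preprocessing as pp
from erpbci import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def session_config():
    return pg.SessionConfig(soa_ms=250.0)


def simulate_run_epochs(profile, seed, *, soa_ms=250.0, reject=True):
    """One six-trial run rendered, filtered, epoched; returns the EpochSet."""
    rng = np.random.default_rng(seed)
    cfg = pg.SessionConfig(soa_ms=soa_ms)
    run = pg.generate_run(cfg, rng)
    eeg = sim.simulate_session(list(run.trials), profile, rng=rng)
    epochs = pp.epoch(pp.bandpass_filter(eeg))
    if reject:
        epochs = pp.reject_artifacts(epochs)
    return epochs


@pytest.fixture(scope="session")
def healthy_run_epochs():
    """A moderately noisy healthy-profile run, shared across tests."""
    return simulate_run_epochs(sim.healthy_profile(), seed=2024)


@pytest.fixture(scope="session")
def healthy_run_features(healthy_run_epochs):
    return pp.extract_features(healthy_run_epochs)


@pytest.fixture(scope="session")
def fitted_classifier(healthy_run_features):
    return dec.fit_slda(healthy_run_features)
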