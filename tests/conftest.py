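import numpy as np
import pytest

from mtsig import SimConfig, simulate_cohort
from mtsig.io import OdorEvent, SessionRecording
from mtsig.pipeline import preprocess_session


@pytest.fixture(scope="session")
def desk_session():
    """One desk-scale synthetic mouse: 8 odors x 20 trials, default mixture."""
    return simulate_cohort(SimConfig(n_mice=1), seed=11)[0]


@pytest.fixture(scope="session")
def desk_features(desk_session):
    """Preprocessed trial matrices for the desk-scale mouse (focus LFP bands)."""
    return preprocess_session(desk_session)


@pytest.fixture(scope="session")
def high_snr_cohort():
    """Three mice with strong, fast, clean responses for recovery studies."""
    return simulate_cohort(SimConfig.high_snr(), seed=101)


@pytest.fixture(scope="session")
def high_snr_features(high_snr_cohort):
    # LFP band power not needed for spike/calcium recovery; skip the wavelets
    return [preprocess_session(rec, bands=()) for rec in high_snr_cohort]


def tiny_session(mouse_id="m00", n_events=4, n_odors=2, seed=0):
    """Handcrafted minimal valid session: constant-ish traces, one unit."""
    rng = np.random.default_rng(seed)
    step = 10.0
    events = [OdorEvent(6.0 + k * step, 1 + k % n_odors, 2.0) for k in range(n_events)]
    dur = events[-1].onset_time + 8.0
    ca = 1.0 + 0.01 * rng.standard_normal(int(dur * 500))
    lfp = rng.standard_normal(int(dur * 1000))
    spikes = np.sort(rng.uniform(0, dur, 200))
    return SessionRecording(mouse_id=mouse_id, ca_trace=ca, lfp_trace=lfp,
                            units=[spikes], events=events)
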