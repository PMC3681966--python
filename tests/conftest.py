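import numpy as np
import pytest

from perceptgamma import simulate as sim
from perceptgamma import timefreq as tf
from perceptgamma.preprocess import preprocess_recording

#: one fixed seed for every stochastic fixture/test in the suite
SEED = 20130613


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def rotation_small():
    """Desk-scale rotating-stimulus dataset (30 trials, 20 perceived)."""
    cfg = sim.SynthConfig(seed=SEED, n_trials=30, n_perceived=20)
    rec, events, behaviour, truth = sim.generate_rotation_dataset(
        cfg, return_truth=True)
    return cfg, rec, events, behaviour, truth


@pytest.fixture(scope="session")
def rsvp_small():
    """Rapid-presentation dataset with a single known 70 Hz burst."""
    burst = sim.BurstSpec(channels=("O1", "OZ", "O2", "PZ"), freq=70.0,
                          onset=0.2, duration=0.4, amplitude=8.0)
    cfg = sim.SynthConfig(paradigm="rsvp", seed=SEED, n_trials=20,
                          bursts=(burst,), hit_probability=1.0)
    rec, events, behaviour, truth = sim.generate_rsvp_dataset(
        cfg, return_truth=True)
    return cfg, rec, events, behaviour, truth


@pytest.fixture(scope="session")
def rsvp_tfr(rsvp_small):
    """Normalized target-locked TFR of the rapid-presentation fixture."""
    _, rec, _, behaviour, _ = rsvp_small
    ep = preprocess_recording(rec, "rsvp", behaviour=behaviour)
    t = tf.tfr_decompose(ep, decim=5)
    return ep, tf.baseline_normalize(t, (-0.2, 0.0))
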