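"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from texchange import sensor as sensor_mod
from texchange import simulate as sim
from texchange import tf as tf_mod


@pytest.fixture(scope="session")
def small_session():
    """A reduced simulated session: 2 blocks x 4 sweeps, default noise."""
    cfg = sim.SessionConfig(n_blocks=2, trials_per_block=4, seed=11)
    wrench, eeg, kin, truth = sim.simulate_participant(cfg, seed=11)
    return {"cfg": cfg, "wrench": wrench, "eeg": eeg, "kin": kin, "truth": truth}


@pytest.fixture(scope="session")
def small_session_events(small_session):
    """Accepted transition events from the small session's sensor stage."""
    w100 = sensor_mod.block_average(small_session["wrench"], 100.0)
    traj = sensor_mod.estimate_contact(w100)
    trials = sensor_mod.epoch_trials(traj, small_session["kin"].onsets)
    return traj, trials, [r.transition for r in trials if r.accepted]


@pytest.fixture(scope="session")
def small_epochs(small_session, small_session_events):
    """Preprocessed, transition-locked epochs from the small session."""
    _, _, events = small_session_events
    rec = tf_mod.preprocess(small_session["eeg"])
    return tf_mod.epoch_eeg(rec, events, participant="p00")


@pytest.fixture(scope="session")
def small_tf(small_epochs):
    """Raw Welch time-frequency power for the small session."""
    return tf_mod.welch_tf(small_epochs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
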