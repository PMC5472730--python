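import numpy as np
import pandas as pd
import pytest

import crossreact as cr
from crossreact.encoding import bin_and_zscore


@pytest.fixture(scope="session")
def task():
    return cr.TaskConfig()


@pytest.fixture(scope="session")
def small_params():
    # scaled-down session for fast unit tests
    return cr.SynthParams(n_neurons=20, trials_per_group=20)


@pytest.fixture(scope="session")
def small_session(task, small_params):
    trials, spikes, gt = cr.generate_session(task, small_params, seed=7)
    return trials, spikes, gt


@pytest.fixture(scope="session")
def small_tensor(small_session):
    trials, spikes, _ = small_session
    return bin_and_zscore(spikes, trials)


def make_tensor(rate, trials, bin_ms=10.0, t_start=0.0):
    """Hand-built RateTensor for constructed-input tests (already 'z-scored')."""
    from crossreact.encoding import RateTensor
    rate = np.asarray(rate, dtype=np.float32)
    n, t, b = rate.shape
    return RateTensor(rate, bin_ms, t_start, trials["trial_id"].to_numpy(),
                      np.arange(n), np.zeros(n), np.ones(n))


def flat_trials(n_trials, span_ms=2000.0, trial_type=None, rng=None):
    """Minimal trial table whose events sit on a fixed grid."""
    if trial_type is None:
        trial_type = np.where(np.arange(n_trials) % 2 == 0, "described",
                              "experienced")
    tt = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "trial_type": trial_type,
        "offer1_size": np.resize([75.0, 100.0, 150.0, 200.0, 250.0], n_trials),
        "offer2_size": np.resize([150.0, 175.0, 200.0], n_trials),
        "offer1_side": "left",
        "chosen_option": 1,
    })
    tt["chosen_size"] = tt["offer1_size"]
    tt["correct"] = tt["chosen_size"] >= tt["offer2_size"]
    tt["fixation_on"] = 0.0
    tt["offer1_cue_on"] = 100.0
    tt["offer1_value_on"] = 200.0
    tt["offer2_on"] = 400.0
    tt["reappear_on"] = 600.0
    tt["choice_made"] = 800.0
    tt["outcome_on"] = 1000.0
    tt["trial_end"] = span_ms
    return tt
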