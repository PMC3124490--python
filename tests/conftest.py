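import numpy as np
import pytest

import likspace as lk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_model():
    """Homogeneous 20 Hz intensity on (0, 1] at 1 ms bins."""
    return lk.IntensityModel(
        lambda_per_bin=np.full(1000, 20.0), delta=0.001, interval=(0.0, 1.0)
    )


def two_pattern_ensembles(n_trials=100, seed=7, delta=0.01):
    """Two stimuli with matched mean rate but opposite temporal profiles.

    Stimulus A fires fast early / slow late, stimulus B the reverse; both
    average 20 Hz over (0, 1], so any rate-only statistic is blind to them.
    """
    rng = np.random.default_rng(seed)
    t = (np.arange(100) + 0.5) * delta
    lam_a = 32.0 - 24.0 * t  # 32 -> 8 Hz, mean 20
    lam_b = 8.0 + 24.0 * t  # 8 -> 32 Hz, mean 20
    out = {}
    for label, lam in (("A", lam_a), ("B", lam_b)):
        model = lk.IntensityModel(lambda_per_bin=lam, delta=delta, interval=(0, 1))
        trains = [
            lk.simulate_spike_train_binned(model, seed=rng, stimulus_id=label, trial_id=i)
            for i in range(n_trials)
        ]
        out[label] = [lk.bin_spike_train(tr, delta) for tr in trains]
    return out, {"A": lam_a, "B": lam_b}


@pytest.fixture(scope="session")
def pattern_data():
    return two_pattern_ensembles()
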