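import itertools
import math

import numpy as np
import pytest

import likspace as lk
from likspace.information import distance_matrix


def bernoulli_enumeration_ssi(models, priors, target):
    """Exact specific information by enumerating every binary response vector.

    Independent oracle: sums p(r|s)*log2[p(r|s)/pbar(r)] over all 2^J
    outcomes of J Bernoulli bins, with probabilities built directly from the
    per-bin rates (never through the package's likelihood code).
    """
    J = models[0].J
    ps = [m.lambda_per_bin * m.delta for m in models]
    total = 0.0
    for bits in itertools.product((0, 1), repeat=J):
        bits = np.array(bits)
        p_cond = [
            np.prod(np.where(bits, p, 1 - p)) for p in ps
        ]
        pbar = float(np.dot(priors, p_cond))
        pc = p_cond[target]
        if pc > 0:
            total += pc * math.log2(pc / pbar)
    return total


class TestDiscreteInformation:
    def test_matching_distributions_carry_zero_information(self):
        assert lk.specific_information_discrete([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_deterministic_responses_give_one_bit(self):
        # two equiprobable stimuli, responses fully separated
        assert lk.specific_information_discrete([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_hand_worked_kl_value(self):
        ssi = lk.specific_information_discrete([0.75, 0.25], [0.5, 0.5])
        assert ssi == pytest.approx(0.18872, abs=1e-5)

    def test_invalid_probability_vectors_rejected(self):
        with pytest.raises(ValueError):
            lk.specific_information_discrete([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError, match="mass where the marginal"):
            lk.specific_information_discrete([1.0, 0.0], [0.0, 1.0])


class TestMutualInformation:
    def test_independent_joint_is_zero(self):
        joint = np.outer([0.4, 0.6], [0.3, 0.7])
        assert lk.mutual_information(joint) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_bijection_gives_log2_p_bits(self):
        joint = np.eye(4) / 4
        assert lk.mutual_information(joint) == pytest.approx(2.0)

    def test_symmetric_two_by_two_table(self):
        joint = np.array([[0.375, 0.125], [0.125, 0.375]])
        assert lk.mutual_information(joint) == pytest.approx(0.18872, abs=1e-5)
        assert lk.mutual_information(joint.T) == pytest.approx(
            lk.mutual_information(joint)
        )

    def test_prior_weighted_specific_informations_reproduce_mi(self, rng):
        joint = rng.uniform(0.01, 1.0, size=(3, 4))
        joint /= joint.sum()
        priors = joint.sum(axis=1)
        marginal = joint.sum(axis=0)
        acc = sum(
            p * lk.specific_information_discrete(joint[i] / p, marginal)
            for i, p in enumerate(priors)
        )
        assert lk.mutual_information(joint) == pytest.approx(acc, abs=1e-10)

    def test_mutual_information_nonnegative_on_random_tables(self, rng):
        for _ in range(20):
            joint = rng.uniform(size=(3, 5))
            joint /= joint.sum()
            assert lk.mutual_information(joint) >= -1e-12


class TestMonteCarloSpecificInformation:
    def test_identical_models_score_zero_for_any_sample(self, rng):
        model = lk.IntensityModel(rng.uniform(5, 30, 5), 0.02, (0, 0.1))
        pd_ = lk.ProjectingDistributions(models=(model, model), form="bernoulli")
        obs = [
            lk.bin_spike_train(lk.simulate_spike_train_binned(model, seed=rng), 0.02)
            for _ in range(20)
        ]
        assert lk.specific_information_mc(pd_, 0, obs) == pytest.approx(0.0, abs=1e-12)

    def test_estimator_approaches_enumeration_with_sample_size(self):
        rng = np.random.default_rng(17)
        J, delta = 6, 0.02
        models = (
            lk.IntensityModel(rng.uniform(5, 45, J), delta, (0, J * delta)),
            lk.IntensityModel(rng.uniform(5, 45, J), delta, (0, J * delta)),
        )
        priors = np.array([0.5, 0.5])
        pd_ = lk.ProjectingDistributions(models=models, priors=priors, form="bernoulli")
        exact = bernoulli_enumeration_ssi(models, priors, target=0)

        def estimate(n):
            obs = [
                lk.bin_spike_train(
                    lk.simulate_spike_train_binned(models[0], seed=rng), delta
                )
                for _ in range(n)
            ]
            return lk.specific_information_mc(pd_, 0, obs)

        err_small = abs(estimate(100) - exact)
        err_large = abs(estimate(10000) - exact)
        assert err_large < 0.05
        assert err_large < err_small

    def test_support_violation_raises(self):
        m1 = lk.IntensityModel([1e-6, 1e-6], 0.1, (0, 0.2))
        m2 = lk.IntensityModel([1e-6, 1e-6], 0.1, (0, 0.2))
        pd_ = lk.ProjectingDistributions(models=(m1, m2), form="bernoulli")
        # both spikes present is astronomically unlikely -> log pbar -> -inf? stays finite
        b = lk.BinnedSpikeTrain([1, 1], 0.1, (0, 0.2))
        assert np.isfinite(lk.specific_information_mc(pd_, 0, [b]))
        with pytest.raises(ValueError):
            lk.specific_information_mc(pd_, 0, [])


class TestStimulusDistance:
    def test_identical_stimuli_at_zero_distance(self):
        assert lk.stimulus_distance(0.42, 0.42) == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0, 2, size=2)
            assert lk.stimulus_distance(a, b) == lk.stimulus_distance(b, a)

    def test_hand_worked_pair(self):
        # conditionals (1,0) vs (0.5,0.5), uniform priors -> pbar=(0.75,0.25)
        i1 = lk.specific_information_discrete([1.0, 0.0], [0.75, 0.25])
        i2 = lk.specific_information_discrete([0.5, 0.5], [0.75, 0.25])
        assert i1 == pytest.approx(math.log2(4 / 3), abs=1e-9)
        assert i2 == pytest.approx(0.2075, abs=1e-4)
        assert lk.stimulus_distance(i1, i2) == pytest.approx(0.2075, abs=1e-4)

    def test_distance_matrix_is_a_pseudometric(self, rng):
        infos = rng.uniform(0, 3, size=6)
        d = distance_matrix(infos)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestSlidingWindowInformation:
    @pytest.fixture(scope="class")
    def step_data(self):
        """Two stimuli identical until a rate step at 300 ms for stimulus B."""
        rng = np.random.default_rng(23)
        delta = 0.005
        J = 200  # (0, 1] at 5 ms
        t = (np.arange(J) + 0.5) * delta
        lam_a = np.full(J, 10.0)
        lam_b = np.where(t > 0.3, 40.0, 10.0)
        data = {}
        for label, lam in (("A", lam_a), ("B", lam_b)):
            model = lk.IntensityModel(lam, delta, (0, 1))
            data[label] = [
                lk.simulate_spike_train_binned(
                    model, seed=rng, stimulus_id=label, trial_id=i
                )
                for i in range(30)
            ]
        return data

    def test_window_count_arithmetic(self, step_data):
        df = lk.sliding_window_information(
            step_data, target="B", delta=0.005, window=0.1, step=0.01
        )
        assert len(df) == 91
        assert df["window_center_s"].iloc[0] == pytest.approx(0.05)
        assert df["window_center_s"].iloc[-1] == pytest.approx(0.95)

    def test_information_peaks_after_the_rate_step(self, step_data):
        df = lk.sliding_window_information(
            step_data, target="B", delta=0.005, window=0.1, step=0.01
        )
        for col in ("bits_likelihood", "bits_rate"):
            peak = df.loc[df[col].idxmax(), "window_center_s"]
            assert peak >= 0.3, col
            # pre-step windows carry almost no information
            pre = df[df["window_center_s"] < 0.25][col].mean()
            post = df[df["window_center_s"] > 0.4][col].mean()
            assert post > pre, col

    def test_flat_rates_give_a_flat_curve(self):
        rng = np.random.default_rng(29)
        delta = 0.005
        model = lk.IntensityModel(np.full(200, 15.0), delta, (0, 1))
        data = {
            lab: [
                lk.simulate_spike_train_binned(model, seed=rng) for _ in range(30)
            ]
            for lab in ("A", "B")
        }
        df = lk.sliding_window_information(
            data, target="A", delta=delta, window=0.1, step=0.05
        )
        # identical generating processes: only Monte-Carlo noise remains
        assert df["bits_likelihood"].abs().max() < 0.25
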