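import math

import numpy as np
import pytest
from scipy import stats

import likspace as lk


def const_model(rate, J=10, delta=0.1):
    return lk.IntensityModel(
        lambda_per_bin=np.full(J, float(rate)), delta=delta, interval=(0.0, J * delta)
    )


class TestProject:
    def test_identical_models_land_on_the_diagonal(self):
        pd_ = lk.ProjectingDistributions(models=(const_model(10), const_model(10)))
        b = lk.BinnedSpikeTrain(
            increments=[0, 1, 0, 0, 1, 0, 0, 0, 0, 0], delta=0.1, interval=(0, 1)
        )
        lv = lk.project(b, pd_)
        assert lv.coords[0] == pytest.approx(lv.coords[1], abs=1e-12)

    def test_projection_dimension_is_p_not_j(self, rng):
        models = tuple(
            lk.IntensityModel(rng.uniform(5, 30, 1000), 0.001, (0, 1))
            for _ in range(3)
        )
        pd_ = lk.ProjectingDistributions(models=models)
        inc = np.zeros(1000, dtype=int)
        inc[::100] = 1
        b = lk.BinnedSpikeTrain(increments=inc, delta=0.001, interval=(0, 1))
        lv = lk.project(b, pd_)
        assert lv.P == 3 < b.J

    def test_hand_worked_two_model_coordinates(self):
        # spike in bin 1 of (0, 0.2] at delta = 0.1:
        # constant 10 Hz: ln(10*0.1) - (1.0 + 1.0)  = -2.0
        # ramp (5, 10) Hz: ln(10*0.1) - (0.5 + 1.0) = -1.5
        const = const_model(10.0, J=2)
        with pytest.warns(RuntimeWarning):
            ramp = lk.IntensityModel(lambda_per_bin=[5.0, 10.0], delta=0.1)
        pd_ = lk.ProjectingDistributions(models=(const, ramp))
        b = lk.BinnedSpikeTrain(increments=[0, 1], delta=0.1, interval=(0, 0.2))
        lv = lk.project(b, pd_)
        assert lv.coords == pytest.approx([-2.0, -1.5], abs=1e-12)

    def test_project_many_stacks_an_m_by_p_array(self, rng):
        pd_ = lk.ProjectingDistributions(models=(const_model(10), const_model(20)))
        obs = []
        for _ in range(7):
            inc = (rng.uniform(size=10) < 0.3).astype(int)
            obs.append(
                lk.BinnedSpikeTrain(increments=inc, delta=0.1, interval=(0, 1))
            )
        assert lk.project_many(obs, pd_).shape == (7, 2)

    def test_incompatible_grid_is_an_error(self):
        pd_ = lk.ProjectingDistributions(models=(const_model(10), const_model(20)))
        b = lk.BinnedSpikeTrain(increments=[0, 1], delta=0.1, interval=(0, 0.2))
        with pytest.raises(ValueError):
            lk.project(b, pd_)


class TestClassify:
    def test_dominant_coordinate_wins_under_uniform_priors(self):
        assert lk.classify(np.array([-10.0, -12.0])) == 0

    def test_log_priors_shift_the_decision(self):
        # -10 + ln 0.25 = -11.386 vs -10.5 + ln 0.75 = -10.788
        assert lk.classify(np.array([-10.0, -10.5]), priors=[0.25, 0.75]) == 1

    def test_exact_tie_resolves_to_smallest_index(self):
        assert lk.classify(np.array([-5.0, -5.0])) == 0

    def test_priors_sum_validation(self):
        with pytest.raises(ValueError):
            lk.ProjectingDistributions(
                models=(const_model(1), const_model(2)), priors=[0.5, 0.6]
            )


class TestConvexity:
    def test_two_model_regions_are_convex(self):
        pd_ = lk.ProjectingDistributions(models=(const_model(10), const_model(20)))
        report = lk.decision_region_convexity_check(pd_, stimulus=0, n_pairs=100, seed=1)
        assert report["passed"] and not report["vacuous"]

    def test_three_random_poisson_models_pass_500_pairs(self, rng):
        models = tuple(
            lk.IntensityModel(rng.uniform(5, 40, 50), 0.02, (0, 1)) for _ in range(3)
        )
        pd_ = lk.ProjectingDistributions(models=models)
        report = lk.decision_region_convexity_check(pd_, stimulus=1, n_pairs=500, seed=7)
        assert report["passed"]
        assert report["n_violations"] == 0

    def test_unreachable_region_is_a_vacuous_pass(self):
        # huge prior imbalance -> stimulus 1 region never sampled
        pd_ = lk.ProjectingDistributions(
            models=(const_model(10), const_model(10)), priors=[1.0, 0.0]
        )
        report = lk.decision_region_convexity_check(pd_, stimulus=1, n_pairs=10, seed=3)
        assert report["passed"] and report["vacuous"]


class TestFisherRatio:
    def test_identical_clusters_score_zero(self, rng):
        pts = rng.normal(size=(40, 3))
        assert lk.fisher_ratio(pts, pts.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_exact_moments(self):
        # means 0 and 2, population variances 1 -> (2)^2 / (1+1) = 2
        a = np.array([[-1.0], [1.0]])
        b = np.array([[1.0], [3.0]])
        assert lk.fisher_ratio(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.normal(size=(30, 2))
        b = rng.normal(loc=2.0, size=(30, 2))
        assert lk.fisher_ratio(5 * a, 5 * b) == pytest.approx(
            lk.fisher_ratio(a, b), rel=1e-9
        )

    def test_singular_scatter_is_ridge_regularized(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])  # rank-1 scatter
        b = np.array([[3.0, 0.0], [4.0, 1.0]])
        with pytest.warns(RuntimeWarning, match="ridge"):
            r = lk.fisher_ratio(a, b)
        assert np.isfinite(r) and r >= 0


class TestSeparability:
    def test_identical_spaces_give_zero_improvement(self, rng):
        pts = rng.normal(size=(60, 2))
        labels = np.repeat(["a", "b", "c"], 20)
        assert lk.separability_improvement(pts, pts, labels) == pytest.approx(0.0)

    def test_temporal_pattern_stimuli_gain_separability_in_likelihood_space(
        self, pattern_data
    ):
        binned, lam = pattern_data
        models = {
            k: lk.fit_intensity(v, q=1e-3) for k, v in binned.items()
        }
        pd_ = lk.ProjectingDistributions(
            models=(models["A"], models["B"]), labels=("A", "B")
        )
        all_obs = binned["A"] + binned["B"]
        labels = np.array(["A"] * len(binned["A"]) + ["B"] * len(binned["B"]))
        lik_pts = lk.project_many(all_obs, pd_)
        obs_pts = np.array([b.increments for b in all_obs], dtype=float)
        # compare the two spaces through their 2-D MDS embeddings
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            e_obs = lk.classical_mds(lk.pairwise_distances(obs_pts)).coords
            e_lik = lk.classical_mds(lk.pairwise_distances(lik_pts)).coords
        improvement = lk.separability_improvement(e_obs, e_lik, labels)
        assert improvement > 0

    def test_blending_models_toward_the_average_reduces_the_improvement(
        self, pattern_data
    ):
        binned, lam = pattern_data
        all_obs = binned["A"] + binned["B"]
        labels = np.array(["A"] * len(binned["A"]) + ["B"] * len(binned["B"]))
        obs_pts = np.array([b.increments for b in all_obs], dtype=float)
        lam_bar = (lam["A"] + lam["B"]) / 2

        def improvement(beta):
            models = tuple(
                lk.IntensityModel(
                    (1 - beta) * lam[k] + beta * lam_bar, 0.01, (0, 1)
                )
                for k in ("A", "B")
            )
            pd_ = lk.ProjectingDistributions(models=models, labels=("A", "B"))
            lik_pts = lk.project_many(all_obs, pd_)
            return lk.separability_improvement(obs_pts, lik_pts, labels)

        assert improvement(0.0) > improvement(0.9)


class TestClassifierEquivalence:
    def test_likelihood_space_rule_matches_observation_space_bayes(self, rng):
        """The linear discriminant on projected coordinates must reproduce the
        plug-in Bayes rule computed directly in the observation space."""
        J, delta = 50, 0.02
        models = tuple(
            lk.IntensityModel(rng.uniform(5, 40, J), delta, (0, 1)) for _ in range(3)
        )
        priors = np.array([0.2, 0.5, 0.3])
        pd_ = lk.ProjectingDistributions(models=models, priors=priors, form="bernoulli")
        for _ in range(100):
            gen = models[rng.integers(3)]
            b = lk.bin_spike_train(
                lk.simulate_spike_train_binned(gen, seed=rng), delta
            )
            lv = lk.project(b, pd_)
            # independent observation-space route via scipy Bernoulli pmf
            scores = [
                stats.bernoulli.logpmf(
                    b.increments, m.lambda_per_bin * delta
                ).sum() + math.log(p)
                for m, p in zip(models, priors)
            ]
            assert lk.classify(lv, priors) == int(np.argmax(scores))


class TestLikelihoodSpaceClassifier:
    def test_held_out_accuracy_on_well_separated_stimuli(self):
        rng = np.random.default_rng(21)
        delta = 0.01
        profiles = {
            "fast": np.full(100, 40.0),
            "slow": np.full(100, 8.0),
            "burst": np.where(np.arange(100) < 30, 60.0, 5.0),
        }
        X_train, y_train, X_test, y_test = [], [], [], []
        for label, lam in profiles.items():
            model = lk.IntensityModel(lam, delta, (0, 1))
            for i in range(60):
                tr = lk.simulate_spike_train_binned(model, seed=rng)
                if i < 40:
                    X_train.append(tr)
                    y_train.append(label)
                else:
                    X_test.append(tr)
                    y_test.append(label)
        clf = lk.LikelihoodSpaceClassifier(delta=delta, q=1e-4)
        clf.fit(X_train, y_train)
        assert clf.score(X_test, np.array(y_test)) >= 0.9
        assert clf.transform(X_test).shape == (len(X_test), 3)

    def test_sklearn_param_interface(self):
        clf = lk.LikelihoodSpaceClassifier(delta=0.005)
        assert clf.get_params()["delta"] == 0.005
        clf.set_params(q=1e-3)
        assert clf.q == 1e-3
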