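import warnings

import numpy as np
import pytest

from hiermotion import classify
from hiermotion.generative import GenerativeParams, stationary_velocity_variance

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="module")
def small_pipeline():
    """Shared generate -> infer -> features run (kept small for speed)."""
    trials = classify.generate_trials(240, seed=7)
    lam = classify.infer_trials(trials)
    feats = classify.compute_features(lam)
    return trials, lam, feats


class TestTrialGeneration:
    def test_roughly_uniform_structures(self):
        trials = classify.generate_trials(400, seed=0)
        counts = {s: (trials.labels == s).sum()
                  for s in classify.STRUCTURES}
        for c in counts.values():
            assert 60 < c < 140     # multinomial around 100

    def test_global_trials_share_one_source(self):
        """With no motion noise, a global trial's three dot streams are
        identical (single shared source, no observation noise added)."""
        table = classify.default_lambda_table(noise_sq=0.0)
        trials = classify.generate_trials(60, seed=1, lambda_table=table)
        g = np.where(trials.labels == "G")[0]
        assert g.size > 0
        v = trials.v[g[0], :, :, 0]
        np.testing.assert_allclose(v[:, 0], v[:, 1], atol=1e-12)
        np.testing.assert_allclose(v[:, 0], v[:, 2], atol=1e-12)

    def test_equal_marginal_variance_across_structures(self):
        """The equal-variance constraint: empirical per-dot velocity
        variance is the same for every structure (checked against the
        stationary closed form, which is structure-independent)."""
        trials = classify.generate_trials(600, seed=3)
        tree = classify.classification_tree()
        ref = None
        for s in classify.STRUCTURES:
            sel = trials.labels == s
            emp = trials.v[sel, :, :, 0].var()
            lam = trials.lambda_true[sel][0]
            params = GenerativeParams(
                lam=lam, tau_s=trials.tau_s, sigma_obs=0.0, dt=trials.dt
            )
            closed = stationary_velocity_variance(tree, params)[0, 0]
            n_eff = sel.sum() * 4.0 / (2 * trials.tau_s) * 3
            se = closed * np.sqrt(2.0 / n_eff)
            assert abs(emp - closed) < 3 * se
            if ref is None:
                ref = closed
            assert closed == pytest.approx(ref)


class TestFeatures:
    def test_pure_shared(self):
        f = classify.compute_features([1, 0, 0, 0, 0, 0, 0])
        assert f[0] == 1.0

    def test_cluster_dominance(self):
        f = classify.compute_features([0, 2, 1, 1, 0.5, 0.5, 0.5])
        assert f[1] == pytest.approx(0.5)

    def test_symmetric_clusters(self):
        f = classify.compute_features([0, 1, 1, 1, 0, 0, 0])
        assert f[1] == pytest.approx(1 / 3)

    def test_degenerate_zeros_return_symmetric_values(self):
        f = classify.compute_features(np.zeros(7))
        np.testing.assert_allclose(f, [1 / 7, 1 / 3, 1 / 3, 1 / 3, 1 / 2])

    def test_permutation_symmetry(self):
        """Relabeling the dots permutes cluster/individual entries; the
        features are invariant."""
        rng = np.random.default_rng(5)
        lam = rng.uniform(0.1, 2.0, size=7)
        f0 = classify.compute_features(lam)
        # swap dots 0 and 1: clusters (01,02,12) -> (01,12,02),
        # individuals (i0,i1,i2) -> (i1,i0,i2)
        perm = [0, 1, 3, 2, 5, 4, 6]
        f1 = classify.compute_features(lam[perm])
        np.testing.assert_allclose(f1, f0, atol=1e-12)
        # swap dots 1 and 2: clusters -> (02,01,12), inds -> (i0,i2,i1)
        perm = [0, 2, 1, 3, 4, 6, 5]
        f2 = classify.compute_features(lam[perm])
        np.testing.assert_allclose(f2, f0, atol=1e-12)


class TestClassifier:
    def test_separable_features_reach_high_accuracy(self):
        rng = np.random.default_rng(0)
        n = 200
        labels = rng.choice(classify.STRUCTURES, n)
        centers = {"I": [0, 0, 0, 0, 0], "G": [3, 0, 0, 0, 0],
                   "C": [0, 3, 0, 0, 0], "H": [0, 0, 3, 0, 0]}
        feats = np.array([centers[l] for l in labels]) \
            + 0.1 * rng.standard_normal((n, 5))
        clf = classify.train_structure_classifier(feats, labels)
        assert (clf.predict(feats) == labels).mean() > 0.98

    def test_label_permutation_gives_chance(self):
        rng = np.random.default_rng(1)
        n = 400
        feats = rng.standard_normal((n, 5))
        labels = rng.choice(classify.STRUCTURES, n)
        clf = classify.train_structure_classifier(feats, labels)
        test_feats = rng.standard_normal((n, 5))
        test_labels = rng.choice(classify.STRUCTURES, n)
        acc = (clf.predict(test_feats) == test_labels).mean()
        assert abs(acc - 0.25) < 0.08

    def test_end_to_end_beats_chance(self, small_pipeline):
        trials, _, feats = small_pipeline
        n_train = 160
        clf = classify.train_structure_classifier(
            feats[:n_train], trials.labels[:n_train]
        )
        acc = (clf.predict(feats[n_train:])
               == trials.labels[n_train:]).mean()
        assert acc > 0.45    # chance is 0.25


class TestChoiceModel:
    def test_full_lapse_is_uniform(self):
        m = classify.ChoiceModel(pi_lapse=1.0, beta_temp=2.0)
        p = classify.choice_probabilities([0.7, 0.1, 0.1, 0.1], m)
        np.testing.assert_allclose(p, 0.25)

    def test_identity_at_unit_temperature(self):
        m = classify.ChoiceModel(pi_lapse=0.0, beta_temp=1.0)
        p_in = np.array([0.5, 0.2, 0.2, 0.1])
        np.testing.assert_allclose(
            classify.choice_probabilities(p_in, m), p_in, atol=1e-12
        )

    def test_zero_temperature_is_bias_softmax(self):
        m = classify.ChoiceModel(pi_lapse=0.0, beta_temp=0.0,
                                 b_G=1.0, b_C=-1.0)
        p = classify.choice_probabilities([0.9, 0.05, 0.03, 0.02], m)
        z = np.exp([0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(p.sum(), 1.0)
        np.testing.assert_allclose(p, z / z.sum())   # beta=0 kills biases

    def test_probabilities_normalized_and_bounded(self):
        rng = np.random.default_rng(2)
        m = classify.ChoiceModel(pi_lapse=0.2, beta_temp=3.0,
                                 b_G=0.5, b_C=-0.3, b_H=0.1)
        raw = rng.dirichlet(np.ones(4), size=100)
        p = classify.choice_probabilities(raw, m)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0.2 / 4 - 1e-12)
        assert np.all(p <= 1 - 0.2 * 3 / 4 + 1e-12)

    def test_parameter_recovery_from_synthetic_responses(self):
        rng = np.random.default_rng(4)
        n = 3000
        p_struct = rng.dirichlet(0.5 * np.ones(4), size=n)
        true = classify.ChoiceModel(pi_lapse=0.1, beta_temp=2.0,
                                    b_G=0.4, b_C=-0.4, b_H=0.0)
        choices = classify.simulate_responses(p_struct, true, seed=8)
        fitted, _ = classify.fit_participant(
            np.log(p_struct), choices, pi_lapse=0.1
        )
        assert fitted.beta_temp == pytest.approx(2.0, abs=0.3)
        assert fitted.b_G == pytest.approx(0.4, abs=0.2)
        assert fitted.b_C == pytest.approx(-0.4, abs=0.2)

    def test_uniform_responses_reach_chance_likelihood(self):
        """Purely random responses are fully explained by the model (via
        lapse and/or zero temperature): the fitted log-likelihood reaches
        the uniform-response bound n log(1/4)."""
        rng = np.random.default_rng(6)
        n = 400
        p_struct = rng.dirichlet(0.5 * np.ones(4), size=n)
        choices = rng.integers(0, 4, size=n)
        out = classify.fit_choice_model(
            {0.05: np.log(p_struct)}, {"p1": choices},
            pi_grid=np.array([0.0, 0.5, 1.0]),
        )
        assert out["log_likelihood"] >= n * np.log(0.25) - 1.0

    def test_loo_log_likelihood_runs(self):
        rng = np.random.default_rng(9)
        n = 30
        p_struct = rng.dirichlet(np.ones(4), size=n)
        m = classify.ChoiceModel(pi_lapse=0.05, beta_temp=1.5)
        choices = classify.simulate_responses(p_struct, m, seed=10)
        ll = classify.loo_log_likelihood(np.log(p_struct), choices, 0.05)
        assert ll > n * np.log(0.25) - 20   # not catastrophically worse


class TestExternalDataGate:
    def test_missing_external_dataset_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="external"):
            classify.load_external_dataset(None)
        with pytest.raises(FileNotFoundError, match="external"):
            classify.load_external_dataset(str(tmp_path / "nope"))
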