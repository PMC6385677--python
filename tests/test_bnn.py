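"""Variational Laplace-prior network: training, prediction, relevance, search."""

import numpy as np
import pandas as pd
import pytest

from modetime.bnn import (
    BNNConfig,
    BNNPosterior,
    BNNResults,
    DissociationTimeBNN,
    hyperparameter_search,
    posterior_predict,
)
from modetime.curation import assemble


def linear_frames(n=2000, d=18, seed=0, coef=None, noise=0.0):
    """Synthetic sparse linear regression task in the frame-table layout."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, d))
    coef = coef if coef is not None else {1: 3.0, 5: -2.0}
    y = sum(c * x[:, j] for j, c in coef.items()) + 50.0
    y = y + noise * rng.normal(size=n)
    df = pd.DataFrame(x, columns=[f"r_{i}" for i in range(d)])
    df.insert(0, "trajectory_id", np.arange(n))
    df.insert(1, "frame_time", 0.0)
    df.insert(2, "label", y)
    return df


QUICK = dict(hidden_layers=(24,), epochs=400, batch_size=128)


def identity_posterior(scale=-60.0):
    """Single linear layer y = x with frozen (near-zero-scale) posterior."""
    return BNNPosterior(
        w_mu=[np.array([[1.0]])],
        w_logsig=[np.array([[scale]])],
        b_mu=[np.zeros(1)],
        b_logsig=[np.full(1, scale)],
        log_noise=0.0,
        activation="tanh",
        x_mean=np.zeros(1),
        x_scale=np.ones(1),
        y_mean=0.0,
        y_scale=1.0,
        feature_names=["r_0"],
    )


class TestTraining:
    def test_sparse_linear_target_learned(self):
        ds = assemble(linear_frames(), seed=0)
        res = DissociationTimeBNN(ds, BNNConfig(seed=0, **QUICK)).fit()
        mad = res.evaluate("val").mad
        assert mad < 0.05 * ds.y_train.std()

    def test_constant_labels_predict_the_constant(self):
        df = linear_frames(n=500, coef={})
        ds = assemble(df, seed=0)
        res = DissociationTimeBNN(
            ds, BNNConfig(seed=0, hidden_layers=(24,), epochs=400, batch_size=128)
        ).fit()
        pred, _ = res.predict(ds.x_test, seed=0)
        np.testing.assert_allclose(pred, 50.0, rtol=0.02)
        # with nothing to explain, weight locations shrink toward zero
        assert np.median(np.abs(res.posterior.w_mu[0])) < 0.05

    def test_identical_seeds_identical_posteriors(self):
        ds = assemble(linear_frames(n=400), seed=0)
        cfg = BNNConfig(seed=9, hidden_layers=(16,), epochs=40)
        a = DissociationTimeBNN(ds, cfg).fit()
        b = DissociationTimeBNN(ds, cfg).fit()
        for wa, wb in zip(a.posterior.w_mu, b.posterior.w_mu):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(a.history, b.history)

    def test_divergence_reported_with_epoch(self):
        ds = assemble(linear_frames(n=300), seed=0)
        cfg = BNNConfig(seed=0, hidden_layers=(16,), epochs=20, learn_rate=1e12)
        with pytest.raises(RuntimeError, match="epoch"):
            DissociationTimeBNN(ds, cfg).fit()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BNNConfig(hidden_layers=(0,))
        with pytest.raises(ValueError):
            BNNConfig(prior_scale=0.0)
        with pytest.raises(ValueError):
            BNNConfig(activation="swish")


class TestPredict:
    def test_zero_scales_give_deterministic_output(self):
        post = identity_posterior()
        x = np.linspace(-0.5, 0.5, 7)[:, None]
        mean, std = posterior_predict(post, x, n_draws=50, seed=0)
        np.testing.assert_allclose(std, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, x[:, 0], atol=1e-12)

    def test_std_nonnegative_and_monte_carlo_error_bounded(self):
        post = identity_posterior(scale=np.log(0.3))
        x = np.linspace(-1, 1, 20)[:, None]
        m1k, s1k = posterior_predict(post, x, n_draws=1000, seed=1)
        m10k, _ = posterior_predict(post, x, n_draws=10_000, seed=2)
        assert np.all(s1k >= 0)
        bound = 4 * s1k / np.sqrt(1000)
        assert np.all(np.abs(m10k - m1k) <= bound + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="features"):
            posterior_predict(identity_posterior(), np.zeros((3, 2)))
        with pytest.raises(ValueError, match="n_draws"):
            posterior_predict(identity_posterior(), np.zeros((3, 1)), n_draws=0)


class TestEvaluate:
    def test_hand_computed_metrics(self):
        """Pairs (yhat, y) = (1,2),(2,2),(3,5),(4,3): MAD 1, RMSD sqrt(6/4), r2 0."""
        res = BNNResults(None, identity_posterior(), np.zeros(1), BNNConfig())
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([2.0, 2.0, 5.0, 3.0])
        m = res.evaluate((x, y), n_draws=1)
        assert m.mad == pytest.approx(1.0)
        assert m.rmsd == pytest.approx(np.sqrt(6 / 4))
        assert m.r2 == pytest.approx(1 - 6 / 6)

    def test_perfect_predictions(self):
        res = BNNResults(None, identity_posterior(), np.zeros(1), BNNConfig())
        y = np.array([1.0, 2.0, 3.0])
        m = res.evaluate((y[:, None], y), n_draws=1)
        assert (m.rmsd, m.mad, m.r2) == (0.0, 0.0, 1.0)

    def test_zero_label_variance_gives_missing_r2(self):
        res = BNNResults(None, identity_posterior(), np.zeros(1), BNNConfig())
        m = res.evaluate((np.array([[1.0], [2.0]]), np.array([3.0, 3.0])), n_draws=1)
        assert np.isnan(m.r2)


class TestRelevance:
    def make_results(self, w):
        post = identity_posterior()
        post.w_mu = [np.asarray(w, dtype=float)]
        post.w_logsig = [np.full_like(post.w_mu[0], -60.0)]
        post.b_mu = [np.zeros(w.shape[1])]
        post.b_logsig = [np.full(w.shape[1], -60.0)]
        post.feature_names = [f"r_{i}" for i in range(w.shape[0])]
        post.x_mean = np.zeros(w.shape[0])
        post.x_scale = np.ones(w.shape[0])
        return BNNResults(None, post, np.zeros(1), BNNConfig())

    def test_zero_row_has_zero_relevance(self):
        w = np.array([[0.0, 0.0], [1.0, -2.0]])
        rel = self.make_results(w).coefficient_magnitudes()
        assert rel.summary[0] == 0.0
        assert rel.summary[1] == pytest.approx(1.5)

    def test_profile_permutes_with_features(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(6, 4))
        rel = self.make_results(w).coefficient_magnitudes()
        perm = rng.permutation(6)
        rel_p = self.make_results(w[perm]).coefficient_magnitudes()
        np.testing.assert_array_equal(rel_p.summary, rel.summary[perm])
        np.testing.assert_array_equal(rel_p.magnitudes, rel.magnitudes[perm])

    def test_planted_sparse_features_top_ranked(self):
        """Two active of 18 features occupy the top-2 ranks across seeds."""
        hits = 0
        for seed in range(20):
            df = linear_frames(n=500, seed=seed, noise=0.1)
            ds = assemble(df, seed=seed)
            res = DissociationTimeBNN(
                ds, BNNConfig(seed=seed, hidden_layers=(24,), epochs=300, batch_size=128)
            ).fit()
            top2 = set(res.coefficient_magnitudes().ranking()[:2].tolist())
            hits += top2 == {1, 5}
        assert hits >= 18


class TestBound:
    def test_zero_weights_zero_bound(self, dataset):
        res = DissociationTimeBNN(dataset, BNNConfig(epochs=1, seed=0)).fit()
        for w in res.posterior.w_mu:
            w[:] = 0.0
        assert res.overfitting_bound() == 0.0

    def test_homogeneous_in_weight_scale(self, fitted):
        base = fitted.overfitting_bound()
        scaled = BNNResults(
            fitted.model,
            BNNPosterior(
                w_mu=[2.0 * w for w in fitted.posterior.w_mu],
                w_logsig=fitted.posterior.w_logsig,
                b_mu=fitted.posterior.b_mu,
                b_logsig=fitted.posterior.b_logsig,
                log_noise=fitted.posterior.log_noise,
                activation=fitted.posterior.activation,
                x_mean=fitted.posterior.x_mean,
                x_scale=fitted.posterior.x_scale,
                y_mean=fitted.posterior.y_mean,
                y_scale=fitted.posterior.y_scale,
                feature_names=fitted.posterior.feature_names,
            ),
            fitted.history,
            fitted.config,
        )
        k = len(fitted.posterior.w_mu)
        assert scaled.overfitting_bound() == pytest.approx(2.0**k * base)

    def test_shrinks_with_root_of_training_size(self, dataset, fitted):
        import copy

        base = fitted.overfitting_bound()
        big = copy.copy(fitted)
        ds4 = copy.copy(dataset)
        ds4.x_train = np.tile(dataset.x_train, (4, 1))
        ds4.y_train = np.tile(dataset.y_train, 4)
        big.model = DissociationTimeBNN(ds4, fitted.config)
        assert big.overfitting_bound() == pytest.approx(base / 2.0)


class TestSearchAndPersistence:
    def test_search_budget_one(self):
        ds = assemble(linear_frames(n=300), seed=0)
        space = {"hidden_layers": [(8,)], "epochs": [20]}
        best, board = hyperparameter_search(space, ds, budget=1, seed=0)
        assert len(board) == 1
        assert best.hidden_layers == (8,)

    def test_best_leads_leaderboard_and_reproducible(self):
        ds = assemble(linear_frames(n=300), seed=0)
        space = {"hidden_layers": [(8,), (16,)], "epochs": [20, 40]}
        best, board = hyperparameter_search(space, ds, budget=4, seed=1)
        assert board["val_mad"].iloc[0] == board["val_mad"].min()
        _, board2 = hyperparameter_search(space, ds, budget=4, seed=1)
        pd.testing.assert_frame_equal(board, board2)

    def test_save_load_round_trip(self, tmp_path, fitted, dataset):
        path = tmp_path / "model.npz"
        fitted.save(path)
        loaded = BNNResults.load(path)
        x = dataset.x_test[:50]
        m0, s0 = fitted.predict(x, n_draws=20, seed=5)
        m1, s1 = loaded.predict(x, n_draws=20, seed=5)
        np.testing.assert_array_equal(m0, m1)
        np.testing.assert_array_equal(s0, s1)
        assert loaded.config.hidden_layers == fitted.config.hidden_layers

    def test_summary_mentions_architecture(self, fitted):
        text = fitted.summary()
        assert "36 -> 64 -> 32 -> 1" in text
        assert "Laplace" in text


def test_uncertainty_tracks_error(fitted, dataset):
    """Predictive spread correlates positively with the absolute error on
    held-out frames."""
    from scipy.stats import spearmanr

    pred, std = fitted.predict(dataset.x_test, seed=7)
    rho = spearmanr(std, np.abs(pred - dataset.y_test)).statistic
    assert rho > 0
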