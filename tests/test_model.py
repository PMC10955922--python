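import numpy as np
import pytest
from sklearn.base import clone

from specblend import (
    SpectralAnalysisModel,
    TrainingDivergenceError,
    gate,
    loss_components,
)


def make_toy_data(rng, m=40, n=25):
    X = rng.normal(size=(m, n))
    Y = np.hstack([rng.integers(0, 2, (m, 3)), rng.uniform(0, 50, (m, 3))])
    return X, Y


class TestForward:
    def test_zero_weights_give_half_probability_and_zero_concentration(self, rng):
        X, Y = make_toy_data(rng)
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(4, 4, 4), epochs=0, random_state=0
        ).fit(X, Y)
        for w in model.coefs_:
            w[:] = 0.0
        pred = model.forward(X[0])
        assert np.allclose(pred.ci_prob, 0.5)
        assert np.allclose(pred.cr_raw, 0.0)
        assert np.allclose(pred.cr_gated, 0.0)  # 0.5 is not > 0.5

    def test_eval_mode_deterministic(self, rng):
        X, Y = make_toy_data(rng)
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(8, 8, 8), epochs=3, batch_size=16,
            learning_rate=0.002, random_state=1,
        ).fit(X, Y)
        a = model.predict(X)
        b = model.predict(X)
        assert np.array_equal(a, b)

    def test_hand_computed_single_unit_chain(self):
        """One input, one hidden unit per layer, hand-set weights."""
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(1, 1, 1), epochs=0, dropout=0.0,
            cr_max=[1, 1, 1], random_state=0,
        ).fit(np.zeros((1, 1)), np.array([[1, 0, 0, 0.5, 0, 0]]))
        model.coefs_ = [
            np.array([[2.0]]),
            np.array([[-1.5]]),
            np.array([[3.0]]),
            np.array([[0.5, -0.5, 1.0, 0.25, 2.0, -1.0]]),
        ]
        model.intercepts_ = [
            np.array([0.5]), np.array([4.0]), np.array([-1.0]),
            np.zeros(6),
        ]
        x = 1.2
        a1 = max(0.0, 2.0 * x + 0.5)          # 2.9
        a2 = max(0.0, -1.5 * a1 + 4.0)        # 0.0 -> relu clips -0.35
        a3 = max(0.0, 3.0 * a2 - 1.0)         # 0.0
        z = a3 * np.array([0.5, -0.5, 1.0, 0.25, 2.0, -1.0])
        pred = model.forward(np.array([x]))
        assert np.allclose(pred.ci_prob, 1 / (1 + np.exp(-z[:3])), rtol=1e-12)
        assert np.allclose(pred.cr_raw, z[3:], rtol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        X, Y = make_toy_data(rng)
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(4,), epochs=0, random_state=0
        ).fit(X, Y)
        with pytest.raises(ValueError, match="length|features"):
            model.forward(np.zeros(7))


class TestLoss:
    def test_bce_at_half_is_ln2(self, rng):
        p = np.full((10, 3), 0.5)
        g = rng.integers(0, 2, (10, 3)).astype(float)
        c = rng.uniform(0, 1, (10, 3))
        lb = loss_components(p, c, g, c, lambda_con=100.0)
        assert lb.identification == pytest.approx(np.log(2.0), rel=1e-12)
        assert lb.concentration == 0.0
        assert lb.total == pytest.approx(np.log(2.0), rel=1e-12)

    def test_lambda_linearity(self, rng):
        p = rng.uniform(0.1, 0.9, (8, 3))
        g = rng.integers(0, 2, (8, 3)).astype(float)
        chat = rng.uniform(0, 1, (8, 3))
        c = rng.uniform(0, 1, (8, 3))
        l1 = loss_components(p, chat, g, c, lambda_con=50.0)
        l2 = loss_components(p, chat, g, c, lambda_con=100.0)
        assert l2.total - l2.identification == pytest.approx(
            2.0 * (l1.total - l1.identification), rel=1e-12
        )

    def test_components_nonnegative_and_nan_rejected(self, rng):
        p = rng.uniform(0.01, 0.99, (5, 3))
        g = rng.integers(0, 2, (5, 3)).astype(float)
        c = rng.uniform(0, 1, (5, 3))
        lb = loss_components(p, c * 0.9, g, c)
        assert lb.identification >= 0 and lb.concentration >= 0
        bad = p.copy()
        bad[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            loss_components(bad, c, g, c)


class TestTraining:
    def test_convergence_on_separable_toy_task(self):
        """Two synthetic gases with disjoint bands, m = 200, 50 epochs."""
        rng = np.random.default_rng(0)
        n = 60
        u1 = np.zeros(n); u1[10:20] = 1.0
        u2 = np.zeros(n); u2[35:50] = 0.5
        m = 200
        present = rng.integers(0, 2, (m, 2))
        conc = present * rng.uniform(1, 10, (m, 2))
        X = conc[:, :1] * u1 + conc[:, 1:] * u2 + rng.normal(0, 0.01, (m, n))
        Y = np.hstack([present, np.zeros((m, 1)), conc, np.zeros((m, 1))])
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(16, 8, 12), epochs=50, batch_size=32,
            learning_rate=0.002, lr_schedule="cosine", random_state=3,
        ).fit(X, Y)
        assert model.history_[-1]["loss"] < 0.1 * model.history_[0]["loss"]

    def test_zero_epochs_returns_untrained_state(self, rng):
        X, Y = make_toy_data(rng)
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(4, 4, 4), epochs=0, random_state=0
        ).fit(X, Y)
        assert model.history_ == []
        assert len(model.coefs_) == 4

    def test_same_seed_identical_history(self, rng):
        X, Y = make_toy_data(rng)
        kw = dict(hidden_layer_sizes=(8, 8, 8), epochs=4, batch_size=16,
                  learning_rate=0.002, random_state=11)
        keys = ("epoch", "loss", "l_iden", "l_con")
        h1 = SpectralAnalysisModel(**kw).fit(X, Y).history_
        h2 = SpectralAnalysisModel(**kw).fit(X, Y).history_
        assert [{k: r[k] for k in keys} for r in h1] == [
            {k: r[k] for k in keys} for r in h2
        ]

    def test_divergence_raises_with_epoch_index(self, rng):
        X, Y = make_toy_data(rng)
        X = X * 1e200  # squared concentration error overflows to inf
        with pytest.raises((TrainingDivergenceError, FloatingPointError)):
            SpectralAnalysisModel(
                hidden_layer_sizes=(4,), epochs=2, random_state=0
            ).fit(X, Y)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            SpectralAnalysisModel(epochs=1).fit(
                np.zeros((0, 5)), np.zeros((0, 6))
            )


class TestGating:
    def test_gating_rule_examples(self):
        ci = np.array([0.4, 0.9, 0.6])
        cr = np.array([3.2, 7.7, 1200.0])
        assert np.allclose(gate(ci, cr), [0.0, 7.7, 1200.0])

    def test_exactly_half_gated_to_zero(self):
        assert gate(np.array([0.5]), np.array([10.0]))[0] == 0.0

    def test_all_below_threshold(self):
        out = gate(np.array([0.1, 0.3, 0.49]), np.array([5.0, 5.0, 5.0]))
        assert np.all(out == 0)

    def test_negative_raw_clipped_when_present(self):
        out = gate(np.array([0.9]), np.array([-2.0]))
        assert out[0] == 0.0

    def test_idempotent(self, rng):
        ci = rng.uniform(0, 1, 50)
        cr = rng.normal(10, 5, 50)
        once = gate(ci, cr)
        assert np.array_equal(gate(ci, once), once)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        model = SpectralAnalysisModel(epochs=7, learning_rate=0.003)
        params = model.get_params()
        assert params["epochs"] == 7
        twin = clone(model)
        assert twin.get_params() == params
        twin.set_params(epochs=9)
        assert twin.epochs == 9 and model.epochs == 7

    def test_score_is_exact_match_ratio(self, rng):
        X, Y = make_toy_data(rng, m=30)
        model = SpectralAnalysisModel(
            hidden_layer_sizes=(6, 6, 6), epochs=2, batch_size=16,
            learning_rate=0.002, random_state=0,
        ).fit(X, Y)
        s = model.score(X, Y)
        assert 0.0 <= s <= 1.0
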