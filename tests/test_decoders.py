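import numpy as np
import pytest

from spikespeech import _nets
from spikespeech.decoders import (
    CASCADE_DEGREE_GRID,
    KALMAN_C_GRID,
    DecoderSpec,
    DenseNNDecoder,
    GRUDecoder,
    KalmanFilterDecoder,
    LSTMDecoder,
    SimpleRNNDecoder,
    WienerCascadeDecoder,
    WienerFilterDecoder,
    make_decoder,
)


class TestWiener:
    def test_exact_linear_recovery(self, rng):
        X = rng.standard_normal((60, 5))
        W = rng.standard_normal((5, 3))
        Y = X @ W + 2.0
        m = WienerFilterDecoder().fit(X, Y)
        np.testing.assert_allclose(m.predict(X), Y, atol=1e-8)
        Xh = rng.standard_normal((20, 5))
        np.testing.assert_allclose(m.predict(Xh), Xh @ W + 2.0, atol=1e-8)

    def test_null_association_near_zero(self, rng):
        X = rng.standard_normal((500, 4))
        Y = rng.standard_normal((500, 2))
        m = WienerFilterDecoder().fit(X[:400], Y[:400])
        pred = m.predict(X[400:])
        for b in range(2):
            assert abs(np.corrcoef(pred[:, b], Y[400:, b])[0, 1]) < 0.15

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        A = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(A.T @ A, A.T @ Y)  # independent normal-equations solve
        m = WienerFilterDecoder().fit(X, Y)
        np.testing.assert_allclose(m.intercept_, beta[0], atol=1e-8)
        np.testing.assert_allclose(m.coef_, beta[1:], atol=1e-8)

    def test_constant_feature_column_tolerated(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        Y = rng.standard_normal((30, 1))
        m = WienerFilterDecoder().fit(X, Y)
        assert np.all(np.isfinite(m.predict(X)))

    def test_width_mismatch_raises(self, rng):
        m = WienerFilterDecoder().fit(rng.standard_normal((20, 3)), rng.standard_normal((20, 1)))
        with pytest.raises(ValueError, match="width"):
            m.predict(rng.standard_normal((5, 4)))


class TestWienerCascade:
    def test_recovers_squared_nonlinearity(self, rng):
        X = rng.standard_normal((400, 4))
        w = rng.standard_normal(4)
        # offset keeps the linear stage informative; the square is the
        # static nonlinearity the cascade's polynomial stage must absorb
        Y = ((X @ w + 0.5) ** 2)[:, None]
        casc = WienerCascadeDecoder(degree=2).fit(X[:300], Y[:300])
        lin = WienerFilterDecoder().fit(X[:300], Y[:300])
        r_c = np.corrcoef(casc.predict(X[300:])[:, 0], Y[300:, 0])[0, 1]
        r_l = np.corrcoef(lin.predict(X[300:])[:, 0], Y[300:, 0])[0, 1]
        assert r_c >= 0.95
        assert r_c > r_l + 0.2

    def test_degree_one_equals_wiener(self, rng):
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 2))
        c = WienerCascadeDecoder(degree=1).fit(X, Y)
        w = WienerFilterDecoder().fit(X, Y)
        np.testing.assert_allclose(c.predict(X), w.predict(X), atol=1e-8)

    @pytest.mark.parametrize("degree", CASCADE_DEGREE_GRID)
    def test_grid_degrees_accepted(self, degree, rng):
        X = rng.standard_normal((40, 2))
        Y = rng.standard_normal((40, 1))
        WienerCascadeDecoder(degree=degree).fit(X, Y)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            WienerCascadeDecoder(degree=0).fit(np.zeros((10, 2)), np.zeros((10, 1)))


class TestKalman:
    def test_beats_persistence_on_linear_gaussian_sim(self, rng):
        A = np.array([[0.95, 0.1], [-0.1, 0.9]])
        H = rng.standard_normal((4, 2))
        n = 600
        x = np.zeros((n, 2))
        for t in range(1, n):
            x[t] = A @ x[t - 1] + 0.3 * rng.standard_normal(2)
        z = x @ H.T + 0.5 * rng.standard_normal((n, 4))
        k = KalmanFilterDecoder(C=1.0).fit(z[:400], x[:400])
        mse_filter = np.mean((k.predict(z[400:]) - x[400:]) ** 2)
        mse_persist = np.mean((x[399:-1] - x[400:]) ** 2)
        assert mse_filter < mse_persist

    @pytest.mark.parametrize("C", KALMAN_C_GRID)
    def test_c_grid_accepted(self, C, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 2))
        KalmanFilterDecoder(C=C).fit(X, Y).predict(X)

    def test_constant_targets_converge(self):
        Y = np.tile([2.0, -1.0], (50, 1))
        X = Y @ np.array([[1.0, 0.5], [0.0, 1.0]])
        k = KalmanFilterDecoder().fit(X, Y)
        np.testing.assert_allclose(k.predict(X)[-1], [2.0, -1.0], atol=1e-6)

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="3 frames"):
            KalmanFilterDecoder().fit(np.zeros((2, 2)), np.zeros((2, 2)))


def _grad_check(net_cls, X, Y, tol):
    rng = np.random.default_rng(7)
    net = net_cls(6, seed=0)
    net.params = net._init_params(np.random.default_rng(1), X.shape[-1], Y.shape[1])
    pred, cache = net._forward(X)
    dY = 2 * (pred - Y) / (Y.shape[0] * Y.shape[1])
    grads = net._backward(cache, dY)
    eps = 1e-6
    worst = 0.0
    for k, v in net.params.items():
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in v.shape)
            v[idx] += eps
            lp = net._loss(net._forward(X)[0], Y)
            v[idx] -= 2 * eps
            lm = net._loss(net._forward(X)[0], Y)
            v[idx] += eps
            num = (lp - lm) / (2 * eps)
            denom = max(1e-6, abs(num) + abs(grads[k][idx]))
            worst = max(worst, abs(num - grads[k][idx]) / denom)
    assert worst < tol


class TestNetworkGradients:
    """Backward passes agree with central finite differences."""

    def test_dense(self, rng):
        _grad_check(_nets.DenseNet, rng.standard_normal((9, 5)), rng.standard_normal((9, 3)), 1e-5)

    @pytest.mark.parametrize("cls", [_nets.SimpleRNNNet, _nets.GRUNet, _nets.LSTMNet])
    def test_recurrent(self, cls, rng):
        _grad_check(cls, rng.standard_normal((9, 4, 5)), rng.standard_normal((9, 3)), 1e-4)


class TestNetworkTraining:
    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((80, 6))
        Y = rng.standard_normal((80, 2))
        preds = []
        for _ in range(2):
            m = DenseNNDecoder(units=8, seed=5, max_epochs=10)
            m.fit(X[:60], Y[:60], X_val=X[60:], Y_val=Y[60:], n_epochs=10)
            preds.append(m.predict(X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_early_stopping_patience_rule(self, rng):
        """Training halts exactly patience epochs after the best validation epoch."""
        X = rng.standard_normal((120, 4))
        W = rng.standard_normal((4, 2))
        Y = X @ W + 0.05 * rng.standard_normal((120, 2))
        # validation from a different regime so val loss turns around quickly
        Xv = rng.standard_normal((30, 4))
        Yv = -(Xv @ W)
        m = DenseNNDecoder(units=8, seed=0, max_epochs=200, patience=5)
        m.fit(X, Y, X_val=Xv, Y_val=Yv)
        log = m.training_log_
        assert len(log) <= 200
        if len(log) < 200:  # stopped early: last improvement exactly patience back
            val = np.array([rec["val_loss"] for rec in log])
            assert val.argmin() == len(log) - 1 - 5

    def test_never_exceeds_max_epochs(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 1))
        m = DenseNNDecoder(units=4, seed=0, max_epochs=7)
        m.fit(X[:30], Y[:30], X_val=X[30:], Y_val=Y[30:])
        assert len(m.training_log_) <= 7

    def test_missing_validation_rejected(self, rng):
        m = DenseNNDecoder(units=4, seed=0)
        with pytest.raises(ValueError, match="validation"):
            m.fit(rng.standard_normal((20, 3)), rng.standard_normal((20, 1)))

    def test_recurrent_reshape_channel_major(self, rng):
        # row = [ch0 @ t0..t2, ch1 @ t0..t2] -> steps axis must interleave channels
        m = SimpleRNNDecoder(units=4, n_steps=3, seed=0)
        X = np.arange(12.0).reshape(2, 6)
        shaped = m._shape(X)
        assert shaped.shape == (2, 3, 2)
        np.testing.assert_array_equal(shaped[0, :, 0], [0, 1, 2])
        np.testing.assert_array_equal(shaped[0, :, 1], [3, 4, 5])

    @pytest.mark.parametrize("cls", [SimpleRNNDecoder, GRUDecoder, LSTMDecoder])
    def test_recurrent_fit_learns_linear_map(self, cls, rng):
        X = rng.standard_normal((300, 8))
        W = rng.standard_normal((8, 2))
        Y = X @ W
        m = cls(units=16, n_steps=2, seed=1, max_epochs=300)
        m.fit(X[:240], Y[:240], X_val=X[240:], Y_val=Y[240:])
        pred = m.predict(X[240:])
        r = np.corrcoef(pred.ravel(), Y[240:].ravel())[0, 1]
        assert r > 0.9


class TestFactory:
    def test_all_algorithms_constructible(self):
        for alg, hp in [
            ("kalman", {"C": 1}), ("wiener", {}), ("wiener_cascade", {"degree": 3}),
            ("dense_nn", {"units": 8}), ("simple_rnn", {"units": 8, "n_steps": 2}),
            ("gru_rnn", {"units": 8, "n_steps": 2}), ("lstm_rnn", {"units": 8, "n_steps": 2}),
        ]:
            make_decoder(DecoderSpec(alg, hp, seed=0))

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown"):
            make_decoder(DecoderSpec("transformer"))

    def test_offset_invariance_with_standardizer(self, rng):
        """Adding a constant to targets is absorbed by the standardizer."""
        from spikespeech.audiofeat import fit_standardizer

        X = rng.standard_normal((100, 4))
        Y = X @ rng.standard_normal((4, 2))
        preds = []
        for offset in (0.0, 7.5):
            Yo = Y + offset
            s = fit_standardizer(Yo[:80])
            m = WienerFilterDecoder().fit(X[:80], s.transform(Yo[:80]))
            preds.append(m.predict(X[80:]))
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-8)
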