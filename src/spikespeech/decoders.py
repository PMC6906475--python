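"""Regression decoders mapping spike-count features to mel-band targets.

Seven algorithms are provided as scikit-learn style regressors:

* :class:`KalmanFilterDecoder` — linear-Gaussian state space whose state
  is the target vector; transition/observation models fitted by least
  squares, predictions from the standard filter recursion. The ``C``
  hyperparameter scales the fitted transition-noise covariance.
* :class:`WienerFilterDecoder` — per-band ordinary least squares with
  intercept on the windowed feature row.
* :class:`WienerCascadeDecoder` — the Wiener filter followed by a fitted
  per-band static polynomial nonlinearity.
* :class:`DenseNNDecoder`, :class:`SimpleRNNDecoder`,
  :class:`GRUDecoder`, :class:`LSTMDecoder` — single-hidden-layer
  networks trained with MSE loss, Adam (dense) or RMSprop (recurrent),
  and validation-loss early stopping (max 2048 epochs, patience 5).

The recurrent decoders consume each windowed feature row as a short
sequence of ``n_steps = span + 1`` time steps by channel; the dense
decoder consumes the row flattened. Targets are standardized mel frames
(rows). All decoders expose ``fit(X, Y, X_val=..., Y_val=...)`` /
``predict(X)`` and are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._nets import DenseNet, GRUNet, LSTMNet, SimpleRNNNet

__all__ = [
    "DecoderSpec",
    "WienerFilterDecoder",
    "WienerCascadeDecoder",
    "KalmanFilterDecoder",
    "DenseNNDecoder",
    "SimpleRNNDecoder",
    "GRUDecoder",
    "LSTMDecoder",
    "make_decoder",
    "fit_wiener",
    "fit_wiener_cascade",
    "fit_kalman",
    "fit_network",
    "predict",
    "ALGORITHMS",
    "KALMAN_C_GRID",
    "CASCADE_DEGREE_GRID",
    "UNITS_GRID",
]

KALMAN_C_GRID = (0.1, 1, 10)
CASCADE_DEGREE_GRID = (2, 3, 4, 5)
UNITS_GRID = (256, 512, 1024, 2048)


@dataclass
class DecoderSpec:
    """Configuration of one decoding algorithm.

    ``algorithm`` is one of ``kalman``, ``wiener``, ``wiener_cascade``,
    ``dense_nn``, ``simple_rnn``, ``gru_rnn``, ``lstm_rnn``;
    ``hyperparameters`` hold the algorithm-specific knobs (``C``,
    ``degree``, ``units``, ``n_steps``).
    """

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


class WienerFilterDecoder(RegressorMixin, BaseEstimator):
    """Per-band ordinary least squares with intercept."""

    def fit(self, X, Y, X_val=None, Y_val=None):
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        A = np.column_stack([np.ones(X.shape[0]), X])
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        self.intercept_ = coef[0]
        self.coef_ = coef[1:]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width differs from training")
        return X @ self.coef_ + self.intercept_


class WienerCascadeDecoder(RegressorMixin, BaseEstimator):
    """Wiener filter plus a per-band static polynomial nonlinearity.

    Parameters
    ----------
    degree : int
        Degree of the per-band polynomial fitted to map the linear
        stage's output onto the target (paper grid 2-5; degree 1 reduces
        to the plain Wiener filter).
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    def fit(self, X, Y, X_val=None, Y_val=None):
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        Y = np.asarray(Y, dtype=np.float64)
        self.linear_ = WienerFilterDecoder().fit(X, Y)
        Z = self.linear_.predict(X)
        self.poly_ = [
            np.polyfit(Z[:, b], Y[:, b], self.degree) for b in range(Y.shape[1])
        ]
        self.n_features_in_ = self.linear_.n_features_in_
        return self

    def predict(self, X):
        Z = self.linear_.predict(X)
        out = np.empty_like(Z)
        for b, pc in enumerate(self.poly_):
            out[:, b] = np.polyval(pc, Z[:, b])
        return out


class KalmanFilterDecoder(RegressorMixin, BaseEstimator):
    """Linear-Gaussian state-space decoder over single-bin features.

    The hidden state is the target (mel frame) vector. The transition
    matrix ``A`` and its noise covariance ``W`` are fitted by least
    squares on consecutive target pairs; the observation matrix ``H``
    (features given state) and noise covariance ``Q`` by regressing
    features on targets. ``C`` scales ``W``, trading smoothness against
    responsiveness. Prediction runs the standard filter recursion over
    the feature sequence in time order.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, Y, X_val=None, Y_val=None):
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if Y.shape[0] < 3:
            raise ValueError("need at least 3 frames to fit the state space")
        Y1, Y2 = Y[:-1], Y[1:]
        # A: Y2 ~ Y1 @ A.T
        A_T, *_ = np.linalg.lstsq(Y1, Y2, rcond=None)
        self.A_ = A_T.T
        resid = Y2 - Y1 @ A_T
        self.W_ = self.C * (resid.T @ resid) / max(resid.shape[0] - 1, 1)
        # H: X ~ Y @ H.T
        H_T, *_ = np.linalg.lstsq(Y, X, rcond=None)
        self.H_ = H_T.T
        resid_o = X - Y @ H_T
        self.Q_ = (resid_o.T @ resid_o) / max(resid_o.shape[0] - 1, 1)
        self.x0_ = Y.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width differs from training")
        m = self.A_.shape[0]
        x = self.x0_.copy()
        P = self.W_.copy()
        out = np.empty((X.shape[0], m))
        I = np.eye(m)
        for t in range(X.shape[0]):
            x = self.A_ @ x
            P = self.A_ @ P @ self.A_.T + self.W_
            S = self.H_ @ P @ self.H_.T + self.Q_
            K = P @ self.H_.T @ np.linalg.pinv(S)  # pinv: robust to degenerate noise
            x = x + K @ (X[t] - self.H_ @ x)
            P = (I - K @ self.H_) @ P
            out[t] = x
        return out


class _NetDecoder(RegressorMixin, BaseEstimator):
    """Shared wrapper over the NumPy networks.

    Inputs and targets are internally z-scored with training-set
    statistics before the network sees them (gradient conditioning);
    predictions are mapped back to target units, so the interface is
    unaffected. Validation data for early stopping pass through the same
    training-set transforms.
    """

    _net_cls: type

    def __init__(self, units: int = 256, seed: int = 0, lr: float = 1e-3,
                 batch_size: int = 128, max_epochs: int = 2048, patience: int = 5):
        self.units = units
        self.seed = seed
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience

    def _shape(self, X):
        return np.asarray(X, dtype=np.float64)

    def _scale_x(self, X):
        return (X - self.x_mean_) / self.x_sd_

    def fit(self, X, Y, X_val=None, Y_val=None, n_epochs: int | None = None):
        X = self._shape(X)
        Y = np.asarray(Y, dtype=np.float64)
        self.x_mean_ = X.mean(axis=0)
        self.x_sd_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean_ = Y.mean(axis=0)
        self.y_sd_ = np.where(Y.std(axis=0) > 0, Y.std(axis=0), 1.0)
        self.net_ = self._net_cls(
            self.units, seed=self.seed, lr=self.lr, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
        )
        Xv = None if X_val is None else self._scale_x(self._shape(X_val))
        Yv = None if Y_val is None else (np.asarray(Y_val, float) - self.y_mean_) / self.y_sd_
        self.net_.fit(self._scale_x(X), (Y - self.y_mean_) / self.y_sd_,
                      Xv, Yv, n_epochs=n_epochs)
        self.training_log_ = self.net_.history
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X):
        X = self._shape(X)
        if int(np.prod(X.shape[1:])) != self.n_features_in_:
            raise ValueError("feature width differs from training")
        return self.net_.predict(self._scale_x(X)) * self.y_sd_ + self.y_mean_


class DenseNNDecoder(_NetDecoder):
    """Dense single-hidden-layer network (ReLU, Adam)."""

    _net_cls = DenseNet


class _RecurrentDecoder(_NetDecoder):
    """Recurrent decoders reshape each row into (n_steps, channels).

    Feature rows are channel-major windows (``channels x n_steps``
    values); they are presented to the recurrent cell as ``n_steps``
    time steps of per-channel counts.
    """

    def __init__(self, units: int = 256, n_steps: int = 1, seed: int = 0,
                 lr: float = 1e-3, batch_size: int = 128,
                 max_epochs: int = 2048, patience: int = 5):
        super().__init__(units=units, seed=seed, lr=lr, batch_size=batch_size,
                         max_epochs=max_epochs, patience=patience)
        self.n_steps = n_steps

    def _shape(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            return X
        n, width = X.shape
        if width % self.n_steps:
            raise ValueError(
                f"feature width {width} not divisible by n_steps {self.n_steps}"
            )
        n_ch = width // self.n_steps
        # channel-major row -> (channels, steps) -> (steps, channels)
        return X.reshape(n, n_ch, self.n_steps).transpose(0, 2, 1)


class SimpleRNNDecoder(_RecurrentDecoder):
    """Simple recurrent network (ReLU, RMSprop)."""

    _net_cls = SimpleRNNNet


class GRUDecoder(_RecurrentDecoder):
    """Gated recurrent unit network (tanh, RMSprop)."""

    _net_cls = GRUNet


class LSTMDecoder(_RecurrentDecoder):
    """Long short-term memory network (tanh, RMSprop)."""

    _net_cls = LSTMNet


ALGORITHMS = {
    "kalman": KalmanFilterDecoder,
    "wiener": WienerFilterDecoder,
    "wiener_cascade": WienerCascadeDecoder,
    "dense_nn": DenseNNDecoder,
    "simple_rnn": SimpleRNNDecoder,
    "gru_rnn": GRUDecoder,
    "lstm_rnn": LSTMDecoder,
}


def make_decoder(spec: DecoderSpec):
    """Instantiate the estimator described by a :class:`DecoderSpec`."""
    if spec.algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {spec.algorithm!r}")
    cls = ALGORITHMS[spec.algorithm]
    kwargs = dict(spec.hyperparameters)
    if spec.algorithm in ("dense_nn", "simple_rnn", "gru_rnn", "lstm_rnn"):
        kwargs.setdefault("seed", spec.seed)
    return cls(**kwargs)


def fit_wiener(X, Y):
    return WienerFilterDecoder().fit(X, Y)


def fit_wiener_cascade(X, Y, degree: int = 3):
    return WienerCascadeDecoder(degree=degree).fit(X, Y)


def fit_kalman(X, Y, C: float = 1.0):
    return KalmanFilterDecoder(C=C).fit(X, Y)


def fit_network(X, Y, spec: DecoderSpec, X_val=None, Y_val=None,
                max_epochs: int = 2048, patience: int = 5):
    kwargs = dict(spec.hyperparameters)
    kwargs["max_epochs"] = max_epochs
    kwargs["patience"] = patience
    kwargs.setdefault("seed", spec.seed)
    cls = ALGORITHMS[spec.algorithm]
    return cls(**kwargs).fit(X, Y, X_val=X_val, Y_val=Y_val)


def predict(model, X):
    """Predict standardized mel frames from features with a fitted decoder."""
    return model.predict(X)
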