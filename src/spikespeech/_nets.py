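"""Minimal NumPy neural networks for regression decoding.

Single-hidden-layer dense and recurrent (simple/GRU/LSTM) networks with
a linear output layer, mean-squared-error loss, minibatch training with
Adam (dense) or RMSprop (recurrent), and validation-loss early stopping
that restores the best-epoch parameters. Hidden activations are ReLU for
the dense and simple recurrent nets and tanh for the gated cells; no
dropout. Everything is seeded and reproducible.

Sequences here are short feature windows (span + 1 bins), so plain
batched backpropagation-through-time in NumPy is fast enough for
desk-scale experiments.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet", "SimpleRNNNet", "GRUNet", "LSTMNet"]


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _orthogonal(rng, n):
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


class _Optimizer:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.state = {k: self._init_slot(v) for k, v in params.items()}

    def _init_slot(self, v):
        raise NotImplementedError

    def step(self, params: dict, grads: dict) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.beta1, self.beta2, self.eps, self.t = beta1, beta2, eps, 0
        super().__init__(params, lr)

    def _init_slot(self, v):
        return [np.zeros_like(v), np.zeros_like(v)]

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for k, g in grads.items():
            m, v = self.state[k]
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            params[k] -= self.lr * corr * m / (np.sqrt(v) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-7):
        self.rho, self.eps = rho, eps
        super().__init__(params, lr)

    def _init_slot(self, v):
        return np.zeros_like(v)

    def step(self, params, grads):
        for k, g in grads.items():
            acc = self.state[k]
            acc += (1.0 - self.rho) * (g * g - acc)
            params[k] -= self.lr * g / (np.sqrt(acc) + self.eps)


class _BaseNet:
    """Shared training loop: minibatches, early stopping, best-epoch restore."""

    optimizer_cls: type[_Optimizer] = Adam

    def __init__(self, n_units: int, seed: int = 0, lr: float = 1e-3,
                 batch_size: int = 128, max_epochs: int = 2048, patience: int = 5):
        if n_units < 1:
            raise ValueError("need at least one hidden unit")
        self.n_units = int(n_units)
        self.seed = int(seed)
        self.lr = lr
        self.batch_size = int(batch_size)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.history: list[dict] = []

    # subclasses: _init_params(rng, n_in, n_out), _forward(X) -> (pred, cache),
    # _backward(cache, dY) -> grads
    def _loss(self, pred, Y):
        return float(np.mean((pred - Y) ** 2))

    def fit(self, X, Y, X_val=None, Y_val=None, n_epochs: int | None = None):
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        rng = np.random.default_rng(self.seed)
        self.params = self._init_params(rng, X.shape[-1], Y.shape[1])
        opt = self.optimizer_cls(self.params, lr=self.lr)
        early = n_epochs is None
        if early and (X_val is None or len(np.asarray(X_val)) == 0):
            raise ValueError("early stopping requires a non-empty validation set")
        n_epochs = self.max_epochs if early else min(n_epochs, self.max_epochs)
        n = X.shape[0]
        best_loss, best_params, since_best = np.inf, None, 0
        self.history = []
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                pred, cache = self._forward(X[sel])
                err = pred - Y[sel]
                train_loss += float(np.sum(err**2)) / Y.shape[1]
                dY = 2.0 * err / (err.shape[0] * err.shape[1])
                grads = self._backward(cache, dY)
                opt.step(self.params, grads)
            record = {"epoch": epoch, "train_loss": train_loss / n}
            if X_val is not None and len(np.asarray(X_val)) > 0:
                val_pred, _ = self._forward(np.asarray(X_val, dtype=np.float64))
                val_loss = self._loss(val_pred, np.asarray(Y_val, dtype=np.float64))
                record["val_loss"] = val_loss
                if early:
                    if val_loss < best_loss - 1e-12:
                        best_loss = val_loss
                        best_params = {k: v.copy() for k, v in self.params.items()}
                        since_best = 0
                    else:
                        since_best += 1
            self.history.append(record)
            if early and since_best >= self.patience:
                break
        if best_params is not None:
            self.params = best_params
        return self

    def predict(self, X):
        pred, _ = self._forward(np.asarray(X, dtype=np.float64))
        return pred


class DenseNet(_BaseNet):
    """Single hidden layer, ReLU activations, linear output; Adam."""

    optimizer_cls = Adam

    def _init_params(self, rng, n_in, n_out):
        return {
            "W1": _glorot(rng, n_in, self.n_units),
            "b1": np.zeros(self.n_units),
            "W2": _glorot(rng, self.n_units, n_out),
            "b2": np.zeros(n_out),
        }

    def _forward(self, X):
        p = self.params
        pre = X @ p["W1"] + p["b1"]
        h = _relu(pre)
        return h @ p["W2"] + p["b2"], (X, pre, h)

    def _backward(self, cache, dY):
        X, pre, h = cache
        p = self.params
        dh = dY @ p["W2"].T
        dpre = dh * (pre > 0)
        return {
            "W2": h.T @ dY,
            "b2": dY.sum(axis=0),
            "W1": X.T @ dpre,
            "b1": dpre.sum(axis=0),
        }


class _RecurrentNet(_BaseNet):
    """Base for recurrent nets: input (n, T, d); output reads the last state."""

    optimizer_cls = RMSprop


class SimpleRNNNet(_RecurrentNet):
    """Vanilla recurrent layer with ReLU hidden activations; RMSprop."""

    def _init_params(self, rng, n_in, n_out):
        return {
            "Wx": _glorot(rng, n_in, self.n_units),
            "Wh": _orthogonal(rng, self.n_units),
            "b": np.zeros(self.n_units),
            "Wy": _glorot(rng, self.n_units, n_out),
            "by": np.zeros(n_out),
        }

    def _forward(self, X):
        p = self.params
        n, T, _ = X.shape
        h = np.zeros((n, self.n_units))
        pres, hs = [], [h]
        for t in range(T):
            pre = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            h = _relu(pre)
            pres.append(pre)
            hs.append(h)
        return h @ p["Wy"] + p["by"], (X, pres, hs)

    def _backward(self, cache, dY):
        X, pres, hs = cache
        p = self.params
        T = X.shape[1]
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wy"] = hs[-1].T @ dY
        g["by"] = dY.sum(axis=0)
        dh = dY @ p["Wy"].T
        for t in range(T - 1, -1, -1):
            dpre = dh * (pres[t] > 0)
            g["Wx"] += X[:, t].T @ dpre
            g["Wh"] += hs[t].T @ dpre
            g["b"] += dpre.sum(axis=0)
            dh = dpre @ p["Wh"].T
        return g


class GRUNet(_RecurrentNet):
    """Gated recurrent unit layer, tanh candidate activations; RMSprop."""

    def _init_params(self, rng, n_in, n_out):
        g = {}
        for gate in ("z", "r", "h"):
            g[f"W{gate}"] = _glorot(rng, n_in, self.n_units)
            g[f"U{gate}"] = _orthogonal(rng, self.n_units)
            g[f"b{gate}"] = np.zeros(self.n_units)
        g["Wy"] = _glorot(rng, self.n_units, n_out)
        g["by"] = np.zeros(n_out)
        return g

    def _forward(self, X):
        p = self.params
        n, T, _ = X.shape
        h = np.zeros((n, self.n_units))
        cache = []
        for t in range(T):
            x = X[:, t]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            hc = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1.0 - z) * h + z * hc
            cache.append((x, h, z, r, hc))
            h = h_new
        return h @ p["Wy"] + p["by"], (cache, h)

    def _backward(self, cache_all, dY):
        cache, h_last = cache_all
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wy"] = h_last.T @ dY
        g["by"] = dY.sum(axis=0)
        dh = dY @ p["Wy"].T
        for x, h_prev, z, r, hc in reversed(cache):
            dz = dh * (hc - h_prev)
            dhc = dh * z
            dh_prev = dh * (1.0 - z)
            dpre_h = dhc * (1.0 - hc**2)
            g["Wh"] += x.T @ dpre_h
            g["Uh"] += (r * h_prev).T @ dpre_h
            g["bh"] += dpre_h.sum(axis=0)
            drh = dpre_h @ p["Uh"].T
            dh_prev += drh * r
            dr = drh * h_prev
            dpre_r = dr * r * (1.0 - r)
            g["Wr"] += x.T @ dpre_r
            g["Ur"] += h_prev.T @ dpre_r
            g["br"] += dpre_r.sum(axis=0)
            dh_prev += dpre_r @ p["Ur"].T
            dpre_z = dz * z * (1.0 - z)
            g["Wz"] += x.T @ dpre_z
            g["Uz"] += h_prev.T @ dpre_z
            g["bz"] += dpre_z.sum(axis=0)
            dh_prev += dpre_z @ p["Uz"].T
            dh = dh_prev
        return g


class LSTMNet(_RecurrentNet):
    """Long short-term memory layer, tanh activations; RMSprop."""

    def _init_params(self, rng, n_in, n_out):
        g = {}
        for gate in ("i", "f", "o", "g"):
            g[f"W{gate}"] = _glorot(rng, n_in, self.n_units)
            g[f"U{gate}"] = _orthogonal(rng, self.n_units)
            g[f"b{gate}"] = np.zeros(self.n_units)
        g["bf"] += 1.0  # forget-gate bias init
        g["Wy"] = _glorot(rng, self.n_units, n_out)
        g["by"] = np.zeros(n_out)
        return g

    def _forward(self, X):
        p = self.params
        n, T, _ = X.shape
        h = np.zeros((n, self.n_units))
        c = np.zeros((n, self.n_units))
        cache = []
        for t in range(T):
            x = X[:, t]
            i = _sigmoid(x @ p["Wi"] + h @ p["Ui"] + p["bi"])
            f = _sigmoid(x @ p["Wf"] + h @ p["Uf"] + p["bf"])
            o = _sigmoid(x @ p["Wo"] + h @ p["Uo"] + p["bo"])
            gg = np.tanh(x @ p["Wg"] + h @ p["Ug"] + p["bg"])
            c_new = f * c + i * gg
            tanh_c = np.tanh(c_new)
            cache.append((x, h, c, i, f, o, gg, tanh_c))
            h = o * tanh_c
            c = c_new
        return h @ p["Wy"] + p["by"], (cache, h)

    def _backward(self, cache_all, dY):
        cache, h_last = cache_all
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wy"] = h_last.T @ dY
        g["by"] = dY.sum(axis=0)
        dh = dY @ p["Wy"].T
        dc = np.zeros_like(dh)
        for x, h_prev, c_prev, i, f, o, gg, tanh_c in reversed(cache):
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * gg
            df = dc * c_prev
            dg = dc * i
            dc = dc * f
            dh = np.zeros_like(dh)
            for name, dgate, act in (
                ("i", di, i), ("f", df, f), ("o", do, o)
            ):
                dpre = dgate * act * (1.0 - act)
                g[f"W{name}"] += x.T @ dpre
                g[f"U{name}"] += h_prev.T @ dpre
                g[f"b{name}"] += dpre.sum(axis=0)
                dh += dpre @ p[f"U{name}"].T
            dpre = dg * (1.0 - gg**2)
            g["Wg"] += x.T @ dpre
            g["Ug"] += h_prev.T @ dpre
            g["bg"] += dpre.sum(axis=0)
            dh += dpre @ p["Ug"].T
        return g
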