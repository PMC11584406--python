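"""Small dense feed-forward regressor with dropout, in plain numpy.

Architecture: fully connected ReLU layers (default widths 2048/512/128,
width-scalable for desk-scale runs), 20% inverted dropout after each hidden
layer, one linear output, Adam optimizer, mean-squared-error loss.  Training
runs for up to a fixed number of epochs and the returned weights are those
of the epoch with the lowest held-out MSE.  Fully deterministic for a fixed
seed.
"""

from __future__ import annotations

import numpy as np


class DropoutMLPRegressor:
    def __init__(self, hidden: tuple[int, ...] = (2048, 512, 128),
                 dropout: float = 0.2, epochs: int = 50,
                 batch_size: int = 128, lr: float = 1e-3,
                 seed: int = 0, standardize: bool = True):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.standardize = standardize
        self.selected_epoch_: int | None = None
        self.val_mse_path_: list[float] = []

    # -- internals ----------------------------------------------------------
    def _init_params(self, n_in: int, rng) -> list[tuple[np.ndarray, np.ndarray]]:
        params = []
        dims = [n_in, *self.hidden, 1]
        for a, b in zip(dims[:-1], dims[1:]):
            w = rng.normal(0, np.sqrt(2.0 / a), size=(a, b))
            params.append((w, np.zeros(b)))
        return params

    def _forward(self, x, params, rng=None):
        """Returns output and per-layer activations; applies inverted
        dropout when *rng* is given (training mode)."""
        acts = [x]
        masks = []
        h = x
        n_hidden = len(params) - 1
        for k, (w, b) in enumerate(params):
            z = h @ w + b
            if k < n_hidden:
                h = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(h)
            else:
                h = z
        return h[:, 0], acts, masks

    def fit(self, X, y, X_val, y_val) -> "DropoutMLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if self.standardize:
            self._x_mu = X.mean(axis=0)
            self._x_sd = X.std(axis=0)
            self._x_sd[self._x_sd == 0] = 1.0
            self._y_mu = y.mean()
            self._y_sd = y.std() or 1.0
            X = (X - self._x_mu) / self._x_sd
            y = (y - self._y_mu) / self._y_sd
        else:
            self._x_mu, self._x_sd = 0.0, 1.0
            self._y_mu, self._y_sd = 0.0, 1.0

        rng = np.random.default_rng([self.seed, 90901])
        params = self._init_params(X.shape[1], rng)
        m_adam = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        v_adam = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_mse = np.inf
        best_params = [(w.copy(), b.copy()) for w, b in params]
        self.val_mse_path_ = []
        n = len(X)
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo: lo + self.batch_size]
                xb, yb = X[idx], y[idx]
                out, acts, masks = self._forward(xb, params, rng=rng)
                grad_out = 2.0 * (out - yb)[:, None] / len(idx)
                grads = [None] * len(params)
                delta = grad_out
                for k in range(len(params) - 1, -1, -1):
                    w, b = params[k]
                    a_prev = acts[k]
                    grads[k] = (a_prev.T @ delta, delta.sum(axis=0))
                    if k > 0:
                        delta = delta @ w.T
                        # backprop through dropout then ReLU
                        if masks[k - 1] is not None:
                            delta = delta * masks[k - 1]
                        delta = delta * (acts[k] > 0)
                t += 1
                new_params = []
                for k, ((w, b), (gw, gb)) in enumerate(zip(params, grads)):
                    mw, mb = m_adam[k]
                    vw, vb = v_adam[k]
                    mw = beta1 * mw + (1 - beta1) * gw
                    mb = beta1 * mb + (1 - beta1) * gb
                    vw = beta2 * vw + (1 - beta2) * gw ** 2
                    vb = beta2 * vb + (1 - beta2) * gb ** 2
                    m_adam[k] = (mw, mb)
                    v_adam[k] = (vw, vb)
                    mhw = mw / (1 - beta1 ** t)
                    mhb = mb / (1 - beta1 ** t)
                    vhw = vw / (1 - beta2 ** t)
                    vhb = vb / (1 - beta2 ** t)
                    new_params.append((w - self.lr * mhw / (np.sqrt(vhw) + eps),
                                       b - self.lr * mhb / (np.sqrt(vhb) + eps)))
                params = new_params
            val_pred, _, _ = self._forward(
                (X_val - self._x_mu) / self._x_sd
                if self.standardize else X_val, params)
            mse = float(np.mean((val_pred * self._y_sd + self._y_mu - y_val) ** 2))
            self.val_mse_path_.append(mse)
            if not np.isfinite(mse):
                raise FloatingPointError(
                    f"non-finite validation loss at epoch {epoch}")
            if mse < best_mse:
                best_mse = mse
                best_params = [(w.copy(), b.copy()) for w, b in params]
                self.selected_epoch_ = epoch
        self._params = best_params
        self.best_val_mse_ = best_mse
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardize:
            X = (X - self._x_mu) / self._x_sd
        out, _, _ = self._forward(X, self._params)
        return out * self._y_sd + self._y_mu
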