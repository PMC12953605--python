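"""A small fully connected classifier: two hidden layers (256, 128), ReLU,
batch normalization and dropout (p = 0.5) after each hidden layer, softmax
output trained with categorical cross-entropy and the Adam optimizer.

Implemented directly on NumPy; the network is small enough that explicit
forward/backward passes are clearer than pulling in a framework, and the
training loop is fully seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y.size, k))
    out[np.arange(y.size), y] = 1.0
    return out


class DenseNetClassifier:
    """Softmax MLP with batch-norm + dropout regularization.

    Parameters mirror conventional defaults: Adam at learning rate 1e-3,
    batch size 32, up to 100 epochs with early stopping on a 10% validation
    split (patience 10).
    """

    def __init__(
        self,
        hidden=(256, 128),
        dropout: float = 0.5,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 100,
        val_fraction: float = 0.1,
        patience: int = 10,
        seed: int = 0,
    ):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    # --- parameter plumbing -------------------------------------------------
    def _init_params(self, n_in: int, n_out: int, rng) -> None:
        sizes = [n_in, *self.hidden, n_out]
        self.W, self.b = [], []
        self.gamma, self.beta = [], []
        self.run_mean, self.run_var = [], []
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            self.W.append(rng.normal(0, np.sqrt(2.0 / fan_in), size=(sizes[i], sizes[i + 1])))
            self.b.append(np.zeros(sizes[i + 1]))
        for h in self.hidden:
            self.gamma.append(np.ones(h))
            self.beta.append(np.zeros(h))
            self.run_mean.append(np.zeros(h))
            self.run_var.append(np.ones(h))
        params = self.W + self.b + self.gamma + self.beta
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._t = 0

    def _params(self):
        return self.W + self.b + self.gamma + self.beta

    # --- forward / backward -------------------------------------------------
    def _forward(self, X, rng=None, training=False):
        cache = {"a": [X], "pre": [], "bn": [], "masks": []}
        h = X
        eps = 1e-5
        momentum = 0.9
        for i, nh in enumerate(self.hidden):
            z = h @ self.W[i] + self.b[i]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean[i] = momentum * self.run_mean[i] + (1 - momentum) * mu
                self.run_var[i] = momentum * self.run_var[i] + (1 - momentum) * var
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            zhat = (z - mu) / np.sqrt(var + eps)
            zb = self.gamma[i] * zhat + self.beta[i]
            a = np.maximum(zb, 0.0)
            if training and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            else:
                mask = None
            cache["pre"].append(z)
            cache["bn"].append((mu, var, zhat))
            cache["masks"].append(mask)
            cache["a"].append(a)
            h = a
        logits = h @ self.W[-1] + self.b[-1]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    def _backward(self, cache, Y):
        n = Y.shape[0]
        eps = 1e-5
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_g = [None] * len(self.gamma)
        grads_be = [None] * len(self.beta)
        delta = (cache["probs"] - Y) / n
        grads_W[-1] = cache["a"][-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        dh = delta @ self.W[-1].T
        for i in reversed(range(len(self.hidden))):
            mask = cache["masks"][i]
            if mask is not None:
                dh = dh * mask
            mu, var, zhat = cache["bn"][i]
            zb_pre_relu = self.gamma[i] * zhat + self.beta[i]
            dh = dh * (zb_pre_relu > 0)
            grads_g[i] = (dh * zhat).sum(axis=0)
            grads_be[i] = dh.sum(axis=0)
            dzhat = dh * self.gamma[i]
            m = dh.shape[0]
            inv_std = 1.0 / np.sqrt(var + eps)
            dz = (inv_std / m) * (
                m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            grads_W[i] = cache["a"][i].T @ dz
            grads_b[i] = dz.sum(axis=0)
            dh = dz @ self.W[i].T
        return grads_W + grads_b + grads_g + grads_be

    def _adam_step(self, grads):
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self._params(), grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # --- sklearn-ish surface ------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], k, rng)
        n = X.shape[0]
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y_idx[tr_idx]
        Xval, yval = X[val_idx], y_idx[val_idx]
        Ytr = _one_hot(ytr, k)
        best_loss, best_state, stale = np.inf, None, 0
        for _ in range(self.epochs):
            order = rng.permutation(len(Xtr))
            for s0 in range(0, len(Xtr), self.batch_size):
                idx = order[s0:s0 + self.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics undefined for a single sample
                _, cache = self._forward(Xtr[idx], rng, training=True)
                grads = self._backward(cache, Ytr[idx])
                self._adam_step(grads)
            if n_val:
                probs, _ = self._forward(Xval, training=False)
                loss = -np.mean(np.log(probs[np.arange(len(yval)), yval] + 1e-12))
                if loss < best_loss - 1e-5:
                    best_loss, stale = loss, 0
                    best_state = [p.copy() for p in self._params()] + [
                        m.copy() for m in self.run_mean
                    ] + [v.copy() for v in self.run_var]
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_state is not None:
            np_params = self._params()
            for p, saved in zip(np_params, best_state[: len(np_params)]):
                p[...] = saved
            extra = best_state[len(np_params):]
            for i in range(len(self.hidden)):
                self.run_mean[i] = extra[i]
                self.run_var[i] = extra[len(self.hidden) + i]
        return self

    def predict_proba(self, X):
        probs, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def get_params(self, deep=True):
        return {
            "hidden": self.hidden, "dropout": self.dropout,
            "learning_rate": self.lr, "batch_size": self.batch_size,
            "epochs": self.epochs, "val_fraction": self.val_fraction,
            "patience": self.patience, "seed": self.seed,
        }
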