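"""A compact NumPy feed-forward network for binary classification.

Supports the two network roles in this package:

* the TracIn classifier — dense hidden layers with ELU activation,
  inverted dropout, L2 weight decay, sigmoid output, binary
  cross-entropy loss, Adam optimisation, and parameter snapshots at
  checkpoint epochs with per-sample gradient access restricted to the
  last two weight layers;
* the DVRL value estimator — ReLU hidden layers trained by single
  reward-weighted log-likelihood steps (REINFORCE).

Everything is float64 and driven by an explicit seed, so training and
gradient evaluation are bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError


def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(z))


def _elu_prime(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(z))


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_prime(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(np.float64)


_ACT = {"elu": (_elu, _elu_prime), "relu": (_relu, _relu_prime)}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Checkpoint:
    epoch: int
    params: list  # list of (W, b) per weight layer
    learning_rate: float


class DenseNet:
    """Fully connected binary classifier with sigmoid output.

    Parameters
    ----------
    layer_sizes
        ``[d_in, h1, ..., 1]``; the final size must be 1.
    activation
        ``"elu"`` or ``"relu"`` for the hidden layers.
    dropout
        Inverted-dropout rate on hidden activations (training only).
    l2
        L2 penalty coefficient on each weight matrix.
    lr
        Adam learning rate.
    """

    def __init__(
        self,
        layer_sizes: list[int],
        activation: str = "elu",
        dropout: float = 0.0,
        l2: float = 0.0,
        lr: float = 1e-3,
        seed: int = 0,
        bias_init: float = 0.0,
    ) -> None:
        if layer_sizes[-1] != 1:
            raise ConfigError("output layer must have size 1")
        self.sizes = list(layer_sizes)
        self.act, self.act_prime = _ACT[activation]
        self.dropout = float(dropout)
        self.l2 = float(l2)
        self.lr = float(lr)
        self.rng = np.random.default_rng(seed)
        self.params: list[tuple[np.ndarray, np.ndarray]] = []
        n_layers = len(self.sizes) - 1
        for li, (fan_in, fan_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            scale = np.sqrt(2.0 / fan_in)  # He init
            W = self.rng.normal(0.0, scale, size=(fan_in, fan_out))
            # a small positive hidden bias keeps narrow ReLU layers alive
            b = np.full(fan_out, bias_init if li < n_layers - 1 else 0.0)
            self.params.append((W, b))
        self._adam_m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.params]
        self._adam_v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.params]
        self._adam_t = 0

    # ------------------------------------------------------------------ #

    def _forward(
        self, X: np.ndarray, params=None, train: bool = False
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Return (p, pre-activations z per layer, inputs a per layer)."""
        params = params if params is not None else self.params
        a = np.asarray(X, dtype=np.float64)
        zs, acts = [], [a]
        n_layers = len(params)
        for li, (W, b) in enumerate(params):
            z = a @ W + b
            zs.append(z)
            if li < n_layers - 1:
                a = self.act(z)
                if train and self.dropout > 0:
                    mask = self.rng.random(a.shape) >= self.dropout
                    a = a * mask / (1.0 - self.dropout)
                acts.append(a)
            else:
                a = _sigmoid(z)
        return a[:, 0], zs, acts

    def predict_proba(self, X: np.ndarray, params=None) -> np.ndarray:
        return self._forward(X, params=params, train=False)[0]

    def loss(self, X: np.ndarray, y: np.ndarray, params=None) -> np.ndarray:
        """Per-sample binary cross-entropy (no L2 term)."""
        p = np.clip(self.predict_proba(X, params), 1e-12, 1 - 1e-12)
        y = np.asarray(y, dtype=np.float64)
        return -(y * np.log(p) + (1 - y) * np.log1p(-p))

    # ------------------------------------------------------------------ #

    def _backward(self, zs, acts, delta_out: np.ndarray):
        """Mean-over-batch gradients from the output-layer delta (n,)."""
        grads = [None] * len(self.params)
        n = delta_out.shape[0]
        delta = delta_out[:, None]  # (n, 1)
        for li in range(len(self.params) - 1, -1, -1):
            W, _ = self.params[li]
            gW = acts[li].T @ delta / n + self.l2 * W
            gb = delta.mean(axis=0)
            grads[li] = (gW, gb)
            if li > 0:
                delta = (delta @ W.T) * self.act_prime(zs[li - 1])
        return grads

    def _adam_update(self, grads, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for li, (gW, gb) in enumerate(grads):
            W, b = self.params[li]
            mW, mb = self._adam_m[li]
            vW, vb = self._adam_v[li]
            mW[:] = beta1 * mW + (1 - beta1) * gW
            mb[:] = beta1 * mb + (1 - beta1) * gb
            vW[:] = beta2 * vW + (1 - beta2) * gW**2
            vb[:] = beta2 * vb + (1 - beta2) * gb**2
            corr1, corr2 = 1 - beta1**t, 1 - beta2**t
            W -= self.lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
            b -= self.lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)

    def train_step(self, X: np.ndarray, targets: np.ndarray, weight: float = 1.0) -> None:
        """One Adam step on ``weight * BCE(targets, p)`` (REINFORCE-style)."""
        p, zs, acts = self._forward(X, train=self.dropout > 0)
        delta_out = weight * (p - np.asarray(targets, dtype=np.float64))
        self._adam_update(self._backward(zs, acts, delta_out))

    def step_from_delta(self, X: np.ndarray, delta_fn) -> np.ndarray:
        """One Adam step from a caller-supplied output delta.

        ``delta_fn(p)`` receives the batch output probabilities and
        returns d(loss)/d(z_out) per sample; enables objectives that are
        not plain cross-entropy (e.g. REINFORCE plus range penalties).
        Returns the probabilities used.
        """
        p, zs, acts = self._forward(X, train=self.dropout > 0)
        self._adam_update(self._backward(zs, acts, delta_fn(p)))
        return p

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 128,
        checkpoint_epochs: tuple[int, ...] = (),
    ) -> list[Checkpoint]:
        """Minibatch training; returns snapshots after each checkpoint epoch."""
        bad = [e for e in checkpoint_epochs if e > epochs]
        if bad:
            raise ConfigError(f"checkpoint epochs {bad} exceed total epochs {epochs}")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = X.shape[0]
        checkpoints: list[Checkpoint] = []
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                self.train_step(X[idx], y[idx])
            if epoch in checkpoint_epochs:
                snap = [(W.copy(), b.copy()) for W, b in self.params]
                checkpoints.append(Checkpoint(epoch, snap, self.lr))
        return checkpoints

    # ------------------------------------------------------------------ #

    def last_two_layer_quantities(self, X: np.ndarray, y: np.ndarray, params=None):
        """Per-sample backprop quantities for the last two weight layers.

        The per-sample BCE gradient w.r.t. the output weights is
        ``delta_out * a_out_in`` and w.r.t. the last hidden layer's
        weights is ``outer(delta_hid, a_hid_in)``; returning the factors
        lets callers form squared norms and pairwise dot products without
        materialising per-sample outer products.

        Returns
        -------
        dict with ``delta_out`` (n,), ``a_out_in`` (n, h), ``delta_hid``
        (n, h_prev_out), ``a_hid_in`` (n, h_prev_in).
        """
        params = params if params is not None else self.params
        p, zs, acts = self._forward(X, params=params, train=False)
        y = np.asarray(y, dtype=np.float64)
        delta_out = p - y
        W_out, _ = params[-1]
        delta_hid = (delta_out[:, None] @ W_out.T) * self.act_prime(zs[-2])
        return {
            "delta_out": delta_out,
            "a_out_in": acts[-1],
            "delta_hid": delta_hid,
            "a_hid_in": acts[-2],
        }
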