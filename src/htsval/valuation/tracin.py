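"""TracIn: influence from loss gradients at training checkpoints.

A feed-forward classifier (three 512-unit ELU hidden layers, dropout
0.5, L2 1e-4, sigmoid output, binary cross-entropy, Adam at 1e-3 by
default) is trained with parameter snapshots at epochs {30, 60, 90}.
Gradients are taken with respect to the last two weight layers only.
With per-sample gradient g_j(c) at checkpoint c and learning rate eta_c:

* ``self`` mode:  score_j = sum_c ||g_j(c)||^2
* ``test`` mode:  score_j = sum_c eta_c * g_j(c) . mean_val g_v(c)
* ``pos``  mode:  as ``test`` with the validation set restricted to
  actives.

Because the last-two-layer gradients factor into outer products
(delta x activation), squared norms and pairwise dot products are formed
from the factors; per-sample gradient vectors are never materialised.
"""

from __future__ import annotations

import numpy as np

from .._nn import DenseNet
from ..exceptions import ConfigError, DegenerateInputError
from .base import (
    ImportanceResults,
    ValuationConfig,
    check_binary_labels,
    fingerprint_array,
)


def _self_contrib(q: dict) -> np.ndarray:
    """||grad||^2 over the last two weight layers (weights + biases)."""
    out_sq = q["delta_out"] ** 2 * ((q["a_out_in"] ** 2).sum(axis=1) + 1.0)
    hid_sq = (q["delta_hid"] ** 2).sum(axis=1) * ((q["a_hid_in"] ** 2).sum(axis=1) + 1.0)
    return out_sq + hid_sq


def _cross_contrib(q_train: dict, q_val: dict) -> np.ndarray:
    """Mean over validation points of grad_train . grad_val."""
    out = (q_train["delta_out"][:, None] * q_val["delta_out"][None, :]) * (
        q_train["a_out_in"] @ q_val["a_out_in"].T + 1.0
    )
    hid = (q_train["delta_hid"] @ q_val["delta_hid"].T) * (
        q_train["a_hid_in"] @ q_val["a_hid_in"].T + 1.0
    )
    return (out + hid).mean(axis=1)


class TracInImportance:
    """Checkpointed gradient-tracing importance model.

    Parameters
    ----------
    X, y
        Training features (real-valued) and binary labels.
    X_val, y_val
        Validation set; required for ``test`` and ``pos`` modes.
    mode
        ``"self"``, ``"test"``, or ``"pos"``.
    hidden
        Hidden layer widths (default three layers of 512).
    epochs, checkpoint_epochs
        Total training epochs and the strictly increasing snapshot
        epochs (default (30, 60, 90)); each checkpoint epoch must not
        exceed ``epochs``.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        mode: str = "self",
        hidden: tuple[int, ...] = (512, 512, 512),
        epochs: int = 90,
        checkpoint_epochs: tuple[int, ...] = (30, 60, 90),
        batch_size: int = 128,
        lr: float = 1e-3,
        dropout: float = 0.5,
        l2: float = 1e-4,
        seed: int = 0,
    ) -> None:
        if mode not in ("self", "test", "pos"):
            raise ConfigError(f"tracin mode must be self|test|pos, got {mode!r}")
        if list(checkpoint_epochs) != sorted(set(checkpoint_epochs)):
            raise ConfigError("checkpoint epochs must be strictly increasing")
        if max(checkpoint_epochs) > epochs:
            raise ConfigError(
                f"checkpoint epoch {max(checkpoint_epochs)} exceeds total epochs {epochs}"
            )
        self.X = np.asarray(X, dtype=np.float64)
        self.y = check_binary_labels(y, "tracin").astype(np.float64)
        self.mode = mode
        if mode in ("test", "pos"):
            if X_val is None or y_val is None or len(np.atleast_1d(y_val)) == 0:
                raise DegenerateInputError(f"tracin {mode} mode needs a validation set")
            self.X_val = np.asarray(X_val, dtype=np.float64)
            self.y_val = np.asarray(y_val, dtype=np.float64)
            if mode == "pos":
                pos = np.flatnonzero(self.y_val == 1)
                if len(pos) == 0:
                    raise DegenerateInputError("tracin pos mode: no active validation samples")
                self.X_val, self.y_val = self.X_val[pos], self.y_val[pos]
        self.hidden = tuple(hidden)
        self.epochs = int(epochs)
        self.checkpoint_epochs = tuple(checkpoint_epochs)
        self.batch_size = int(batch_size)
        self.lr = float(lr)
        self.dropout = float(dropout)
        self.l2 = float(l2)
        self.seed = int(seed)
        self.net_: DenseNet | None = None
        self.checkpoints_ = None

    def _train(self) -> None:
        if self.checkpoints_ is not None:
            return
        net = DenseNet(
            [self.X.shape[1], *self.hidden, 1],
            activation="elu",
            dropout=self.dropout,
            l2=self.l2,
            lr=self.lr,
            seed=self.seed,
        )
        self.checkpoints_ = net.fit(
            self.X,
            self.y,
            epochs=self.epochs,
            batch_size=self.batch_size,
            checkpoint_epochs=self.checkpoint_epochs,
        )
        self.net_ = net

    def fit(self) -> ImportanceResults:
        self._train()
        scores = np.zeros(len(self.y))
        for ckpt in self.checkpoints_:
            q_train = self.net_.last_two_layer_quantities(self.X, self.y, ckpt.params)
            if self.mode == "self":
                scores += _self_contrib(q_train)
            else:
                q_val = self.net_.last_two_layer_quantities(
                    self.X_val, self.y_val, ckpt.params
                )
                scores += ckpt.learning_rate * _cross_contrib(q_train, q_val)

        config = ValuationConfig(
            "tracin",
            self.mode,
            self.seed,
            {
                "hidden": self.hidden,
                "epochs": self.epochs,
                "checkpoint_epochs": self.checkpoint_epochs,
                "batch_size": self.batch_size,
                "lr": self.lr,
                "dropout": self.dropout,
                "l2": self.l2,
            },
        )
        return ImportanceResults(
            scores,
            config,
            diagnostics={"n_checkpoints": len(self.checkpoints_)},
            model_fingerprint=fingerprint_array(scores),
        )


def tracin_scores(
    X, y, X_val=None, y_val=None, mode: str = "self", seed: int = 0, **kwargs
) -> ImportanceResults:
    """One-call TracIn importance (see :class:`TracInImportance`)."""
    return TracInImportance(X, y, X_val, y_val, mode=mode, seed=seed, **kwargs).fit()
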