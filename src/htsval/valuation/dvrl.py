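"""DVRL: data valuation with reinforcement learning.

A value-estimator network (ReLU MLP; two hidden layers of width 100, a
combined layer of width 10, Adam at 0.01) maps each training sample's
[features, label, marginal] triple — where *marginal* is the absolute
gap |y - p_full(x)| between the label and a predictor fit on the full
training set, a direct mislabel/outlier cue — to a selection
probability.  Each iteration draws a training minibatch, samples a
Bernoulli selection vector from the probabilities, fits a LightGBM
predictor on the selected samples, and scores area-under-ROC on the
validation set.  The estimator is updated by the score-function
(REINFORCE) gradient of the reward — the ROC-AUC minus an exponential
moving-average baseline — plus a range penalty that pushes the mean
selection probability back inside [0.1, 0.9] so the policy cannot
collapse to select-all or select-none.  Final scores are the
estimator's selection probabilities on the full training set, in [0, 1].

Selection probabilities are additionally clipped to [1e-3, 1 - 1e-3] as
an exploration floor during sampling.  Iteration count and batch size
default to a desk scale (200 / 1000) and are configurable upward.
"""

from __future__ import annotations

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, cross_val_predict

from .._nn import DenseNet
from ..exceptions import DegenerateInputError
from .base import (
    ImportanceResults,
    ValuationConfig,
    check_binary_labels,
    fingerprint_array,
)

_CLIP = (1e-3, 1.0 - 1e-3)


class DVRLImportance:
    """Reinforcement-learned selection-probability importance model."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        iterations: int = 200,
        batch_size: int = 1000,
        hidden: int = 100,
        combined: int = 10,
        lr: float = 0.01,
        baseline_decay: float = 0.9,
        range_penalty: float = 10.0,
        n_policy_samples: int = 4,
        seed: int = 0,
        predictor_params: dict | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=np.float64)
        self.y = check_binary_labels(y, "dvrl").astype(np.float64)
        self.X_val = np.asarray(X_val, dtype=np.float64)
        self.y_val = np.asarray(y_val)
        if len(np.unique(self.y_val)) < 2:
            raise DegenerateInputError(
                "dvrl: validation labels are constant, reward undefined"
            )
        self.iterations = int(iterations)
        self.batch_size = int(batch_size)
        self.hidden = int(hidden)
        self.combined = int(combined)
        self.lr = float(lr)
        self.baseline_decay = float(baseline_decay)
        self.range_penalty = float(range_penalty)
        self.n_policy_samples = int(n_policy_samples)
        self.seed = int(seed)
        self.predictor_params = dict(predictor_params or {})

    def _predictor(self) -> LGBMClassifier:
        params = dict(random_state=self.seed, n_jobs=1, verbose=-1)
        params.update(self.predictor_params)
        return LGBMClassifier(**params)

    def fit(self) -> ImportanceResults:
        n, d = self.X.shape
        # marginal cue: |y - p(x)| with out-of-fold predictions, so a
        # mislabeled sample shows a large gap instead of being memorised
        oof = cross_val_predict(
            self._predictor(),
            self.X,
            self.y.astype(int),
            cv=KFold(n_splits=5, shuffle=False),
            method="predict_proba",
        )[:, 1]
        marginal = np.abs(self.y - oof)
        full = self._predictor()
        full.fit(self.X, self.y.astype(int))
        inputs = np.concatenate(
            [self.X, self.y[:, None], marginal[:, None]], axis=1
        )
        est = DenseNet(
            [d + 2, self.hidden, self.hidden, self.combined, 1],
            activation="relu",
            dropout=0.0,
            l2=0.0,
            lr=self.lr,
            seed=self.seed,
            bias_init=0.1,
        )
        rng = np.random.default_rng([self.seed, 7919])
        # baseline: the full-data predictor's own validation AUC, tracked
        # as a slow moving average so reward = "does this subset beat
        # training on everything"
        baseline = roc_auc_score(self.y_val, full.predict_proba(self.X_val)[:, 1])
        rewards = []
        rvar = 0.0  # running second moment for reward normalisation
        for _ in range(self.iterations):
            idx = (
                rng.choice(n, size=self.batch_size, replace=False)
                if self.batch_size < n
                else np.arange(n)
            )
            probs = np.clip(est.predict_proba(inputs[idx]), *_CLIP)
            sels, scaled = [], []
            for _ in range(self.n_policy_samples):
                sel = (rng.random(len(idx)) < probs).astype(np.float64)
                chosen = idx[sel == 1]
                if len(chosen) and len(np.unique(self.y[chosen])) == 2:
                    model = self._predictor()
                    model.fit(self.X[chosen], self.y[chosen].astype(int))
                    auc = roc_auc_score(
                        self.y_val, model.predict_proba(self.X_val)[:, 1]
                    )
                else:
                    auc = 0.5  # degenerate selection scores as a random ranker
                raw_reward = auc - baseline
                rewards.append(auc)
                # normalise by the running reward scale: keeps the policy
                # gradient usable when AUC differences are small
                rvar = (
                    self.baseline_decay * rvar
                    + (1 - self.baseline_decay) * raw_reward**2
                )
                scale = max(np.sqrt(rvar), 0.02)  # floor caps early amplification
                sels.append(sel)
                scaled.append(float(np.clip(raw_reward / scale, -2.0, 2.0)))
                baseline = (
                    self.baseline_decay * baseline + (1 - self.baseline_decay) * auc
                )

            # maximize mean_k reward_k * log pi(sel_k)  <=>  minimize the
            # reward-weighted BCE, plus the mean-probability range penalty
            def _delta(p, sels=sels, scaled=scaled):
                g = np.zeros_like(p)
                for sel, r in zip(sels, scaled):
                    g += r * (p - sel)
                g /= len(sels)
                pm = p.mean()
                push = float(pm > 0.9) - float(pm < 0.1)
                return g + self.range_penalty * push * p * (1 - p)

            est.step_from_delta(inputs[idx], _delta)

        scores = np.clip(est.predict_proba(inputs), 0.0, 1.0)
        config = ValuationConfig(
            "dvrl",
            "test",
            self.seed,
            {
                "iterations": self.iterations,
                "batch_size": self.batch_size,
                "hidden": self.hidden,
                "combined": self.combined,
                "lr": self.lr,
            },
        )
        return ImportanceResults(
            scores,
            config,
            diagnostics={
                "final_baseline": float(baseline),
                "mean_reward_auc": float(np.mean(rewards)),
            },
            model_fingerprint=fingerprint_array(scores),
        )


def dvrl_scores(X, y, X_val, y_val, seed: int = 0, **kwargs) -> ImportanceResults:
    """One-call DVRL importance (see :class:`DVRLImportance`)."""
    return DVRLImportance(X, y, X_val, y_val, seed=seed, **kwargs).fit()
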