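"""MVS-A self-importance from per-round boosting gradients.

A LightGBM binary classifier is trained on the full training set
(100 rounds, lambda regularization 1.0, column subsampling 0.95 by
default, initial raw score 0 so the first round sees p = 0.5 for every
sample).  At every boosting round the running raw predictions give each
sample's log-loss gradient g = p - y and Hessian h = p(1 - p); the
importance of sample j is the summed regularized gradient magnitude

    score_j = sum_rounds sqrt(g_j^2 + lambda * h_j^2)

— the quantity minimal-variance sampling uses to pick large-gradient
samples.  High scores mark samples the booster keeps struggling with:
among primary actives these are dominated by false positives.

The per-round combination lives in :func:`_round_contribution` so the
exact functional form is isolated and swappable.
"""

from __future__ import annotations

import numpy as np
from lightgbm import LGBMClassifier

from ..exceptions import DegenerateInputError
from .base import (
    ImportanceResults,
    ValuationConfig,
    check_binary_labels,
    fingerprint_array,
)


def _round_contribution(g: np.ndarray, h: np.ndarray, reg_lambda: float) -> np.ndarray:
    """Per-sample score contribution of one boosting round."""
    return np.sqrt(g**2 + reg_lambda * h**2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class MVSAImportance:
    """Gradient-boosting self-importance model.

    Parameters
    ----------
    X, y
        Training features (n x d) and binary labels.
    n_rounds
        Boosting iterations (default 100).
    reg_lambda
        L2 leaf regularization, also the Hessian weight in the score.
    colsample
        Per-tree column subsampling fraction (default 0.95).
    seed
        Drives the booster's randomness.
    lgbm_params
        Extra LightGBM keyword overrides (e.g. ``min_child_samples`` for
        tiny fixtures).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        n_rounds: int = 100,
        reg_lambda: float = 1.0,
        colsample: float = 0.95,
        seed: int = 0,
        lgbm_params: dict | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=np.float64)
        if not np.all(np.isfinite(self.X)):
            raise DegenerateInputError("mvsa: features contain non-finite values")
        self.y = check_binary_labels(y, "mvsa")
        self.n_rounds = int(n_rounds)
        self.reg_lambda = float(reg_lambda)
        self.colsample = float(colsample)
        self.seed = int(seed)
        self.lgbm_params = dict(lgbm_params or {})
        self.model_: LGBMClassifier | None = None

    def _make_model(self) -> LGBMClassifier:
        params = dict(
            n_estimators=self.n_rounds,
            reg_lambda=self.reg_lambda,
            colsample_bytree=self.colsample,
            random_state=self.seed,
            boost_from_average=False,
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
        )
        params.update(self.lgbm_params)
        return LGBMClassifier(**params)

    def fit(self) -> ImportanceResults:
        model = self._make_model()
        model.fit(self.X, self.y)
        self.model_ = model
        booster = model.booster_
        n_trees = booster.num_trees()

        scores = np.zeros(len(self.y))
        raw = np.zeros(len(self.y))  # boost_from_average=False => init score 0
        per_round_first = None
        for t in range(n_trees):
            # state *before* round t+1: gradient/Hessian the round trains on
            p = _sigmoid(raw)
            g = p - self.y
            h = p * (1.0 - p)
            contrib = _round_contribution(g, h, self.reg_lambda)
            if t == 0:
                per_round_first = contrib.copy()
            scores += contrib
            raw += booster.predict(
                self.X, start_iteration=t, num_iteration=1, raw_score=True
            )

        config = ValuationConfig(
            "mvsa",
            "self",
            self.seed,
            {
                "n_rounds": self.n_rounds,
                "reg_lambda": self.reg_lambda,
                "colsample": self.colsample,
                **self.lgbm_params,
            },
        )
        return ImportanceResults(
            scores,
            config,
            diagnostics={
                "n_trees": n_trees,
                "round1_contribution": per_round_first,
            },
            model_fingerprint=fingerprint_array(scores),
        )


def mvsa_scores(
    X: np.ndarray, y: np.ndarray, seed: int = 0, **kwargs
) -> ImportanceResults:
    """One-call MVS-A importance (see :class:`MVSAImportance`)."""
    return MVSAImportance(X, y, seed=seed, **kwargs).fit()
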