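"""Exact Shapley values of the K-nearest-neighbor utility (test-importance).

For a validation point t and training points sorted by ascending distance
(alpha_1 nearest, ties broken by ascending index), the Shapley value of
each training point under the KNN utility

    v(S) = (1/K) * sum_{k=1..min(K,|S|)} 1[y_{alpha_k(S)} = y_t],  v(empty) = 0

admits the closed-form recursion (farthest to nearest)

    s_{alpha_N} = 1[y_{alpha_N} = y_t] / N
    s_{alpha_i} = s_{alpha_{i+1}}
                  + (1[y_{alpha_i}=y_t] - 1[y_{alpha_{i+1}}=y_t]) * min(K, i) / (K * i)

The final importance of training point j is the mean of its per-validation-
point Shapley values.  Because the exact computation scales poorly with
training size, the majority class is first randomly undersampled to a
minority:majority ratio (default 0.2, seeded); removed samples receive
score 0 and are flagged in the diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import ConfigError, DegenerateInputError
from .base import (
    ImportanceResults,
    ValuationConfig,
    check_binary_labels,
    fingerprint_array,
)


@dataclass
class KNNConfig:
    k: int = 5
    undersample_ratio: float = 0.2
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("K must be >= 1")
        if not (0 < self.undersample_ratio <= 1):
            raise ConfigError("undersample_ratio must lie in (0, 1]")
        if self.distance != "euclidean":
            raise ConfigError(f"unsupported distance {self.distance!r}")


def undersample_majority(
    y: np.ndarray, ratio: float, seed: int
) -> np.ndarray:
    """Indices kept after randomly downsampling the majority class so that
    minority:majority = ``ratio`` (all minority samples are kept)."""
    y = np.asarray(y)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    minority, majority = (1, 0) if n1 <= n0 else (0, 1)
    n_min = min(n1, n0)
    n_maj_target = min(max(n1, n0), int(np.ceil(n_min / ratio)))
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(y == majority)
    keep_maj = rng.choice(maj_idx, size=n_maj_target, replace=False)
    kept = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
    return kept


def knn_shapley_single(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: int,
    k: int,
) -> np.ndarray:
    """Per-training-point Shapley values for one validation point."""
    n = len(y_train)
    if k > n:
        raise ConfigError(f"K={k} exceeds number of training points {n}")
    dist = np.linalg.norm(X_train - x_val[None, :], axis=1)
    order = np.lexsort((np.arange(n), dist))  # ascending distance, ties by index
    match = (y_train[order] == y_val).astype(np.float64)

    s_sorted = np.empty(n)
    s_sorted[n - 1] = match[n - 1] / n
    for i in range(n - 1, 0, -1):  # alpha_i, 1-based i = index i-1..1
        s_sorted[i - 1] = s_sorted[i] + (match[i - 1] - match[i]) * min(k, i) / (k * i)

    scores = np.empty(n)
    scores[order] = s_sorted
    return scores


class KNNShapleyImportance:
    """KNN-Shapley test-importance model.

    Scores each training compound by its average exact Shapley value of
    the KNN utility over the validation points, after seeded majority-
    class undersampling.
    """

    def __init__(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        knn: KNNConfig | None = None,
        seed: int = 0,
    ) -> None:
        if len(np.atleast_1d(y_val)) == 0:
            raise DegenerateInputError("knn_shapley: validation set is empty")
        self.X_train = np.asarray(X_train, dtype=np.float64)
        self.y_train = np.asarray(y_train).astype(np.int64)
        self.X_val = np.asarray(X_val, dtype=np.float64)
        self.y_val = np.asarray(y_val).astype(np.int64)
        self.knn = knn or KNNConfig()
        self.seed = int(seed)

    def fit(self) -> ImportanceResults:
        kept = undersample_majority(self.y_train, self.knn.undersample_ratio, self.seed)
        check_binary_labels(self.y_train[kept], "knn_shapley after undersampling")
        Xk, yk = self.X_train[kept], self.y_train[kept]
        if self.knn.k > len(kept):
            raise ConfigError("K exceeds the undersampled training size")

        acc = np.zeros(len(kept))
        for xv, yv in zip(self.X_val, self.y_val):
            acc += knn_shapley_single(Xk, yk, xv, int(yv), self.knn.k)
        acc /= len(self.y_val)

        scores = np.zeros(len(self.y_train))
        scores[kept] = acc
        removed = np.setdiff1d(np.arange(len(self.y_train)), kept)
        config = ValuationConfig(
            "knn_shapley",
            "test",
            self.seed,
            {"k": self.knn.k, "undersample_ratio": self.knn.undersample_ratio},
        )
        return ImportanceResults(
            scores,
            config,
            diagnostics={
                "n_kept": len(kept),
                "undersampled_out": removed,
                "kept_idx": kept,
            },
            model_fingerprint=fingerprint_array(scores),
        )


def knn_shapley_scores(
    X_train, y_train, X_val, y_val, knn: KNNConfig | None = None, seed: int = 0
) -> ImportanceResults:
    """One-call KNN-Shapley importance (see :class:`KNNShapleyImportance`)."""
    return KNNShapleyImportance(X_train, y_train, X_val, y_val, knn, seed).fit()
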