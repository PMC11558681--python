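"""KNN-Shapley: exact-enumeration oracle, efficiency, and contracts."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

from htsval.exceptions import ConfigError
from htsval.valuation.knn_shapley import (
    KNNConfig,
    KNNShapleyImportance,
    knn_shapley_single,
    undersample_majority,
)


def brute_force_shapley(X, y, xv, yv, k):
    """Subset-enumeration Shapley values of the KNN utility (v(empty)=0)."""
    n = len(y)
    dist = np.linalg.norm(X - xv, axis=1)

    def utility(S):
        if not S:
            return 0.0
        S = sorted(S, key=lambda i: (dist[i], i))
        return sum(int(y[i] == yv) for i in S[:k]) / k

    phi = np.zeros(n)
    for j in range(n):
        others = [i for i in range(n) if i != j]
        for r in range(n):
            for S in combinations(others, r):
                w = factorial(r) * factorial(n - r - 1) / factorial(n)
                phi[j] += w * (utility(set(S) | {j}) - utility(set(S)))
    return phi


@pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (6, 2, 1), (7, 3, 2), (8, 1, 3)])
def test_recursion_equals_exhaustive_enumeration(n, k, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = rng.integers(0, 2, n)
    xv = rng.normal(size=3)
    yv = int(rng.integers(0, 2))
    exact = brute_force_shapley(X, y, xv, yv, k)
    rec = knn_shapley_single(X, y, xv, yv, k)
    assert np.abs(exact - rec).max() < 1e-10


def test_base_case_single_training_point():
    X = np.zeros((1, 2))
    assert knn_shapley_single(X, np.array([1]), np.zeros(2), 1, 1)[0] == 1.0
    assert knn_shapley_single(X, np.array([0]), np.zeros(2), 1, 1)[0] == 0.0


def test_efficiency_sum_equals_full_utility():
    """Per validation point, sum of values = v(full) - v(empty)."""
    rng = np.random.default_rng(4)
    for k in (1, 3, 5):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        xv = rng.normal(size=4)
        yv = 1
        s = knn_shapley_single(X, y, xv, yv, k)
        dist = np.linalg.norm(X - xv, axis=1)
        order = np.lexsort((np.arange(30), dist))
        v_full = (y[order[:k]] == yv).sum() / k
        assert abs(s.sum() - v_full) < 1e-10


def test_duplicate_training_points_get_identical_scores():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 3.0], [5.0, 1.0]])
    y = np.array([1, 1, 0, 1])
    s = knn_shapley_single(X, y, np.zeros(2), 1, 2)
    assert s[0] == pytest.approx(s[1], abs=1e-12)


def test_undersampling_ratio_and_flags():
    y = np.zeros(120, dtype=int)
    y[:20] = 1
    kept = undersample_majority(y, ratio=0.2, seed=0)
    assert (y[kept] == 1).sum() == 20
    assert (y[kept] == 0).sum() == 100  # ceil(20 / 0.2)

    rng = np.random.default_rng(0)
    X = rng.normal(size=(120, 4))
    Xv, yv = rng.normal(size=(5, 4)), np.array([1, 0, 1, 0, 1])
    res = KNNShapleyImportance(X, y, Xv, yv, KNNConfig(k=3), seed=1).fit()
    removed = res.diagnostics["undersampled_out"]
    assert len(removed) == 0 or np.all(res.scores[removed] == 0.0)
    assert len(res.scores) == 120


def test_k_larger_than_train_errors():
    X = np.zeros((3, 2))
    with pytest.raises(ConfigError):
        knn_shapley_single(X, np.array([0, 1, 0]), np.zeros(2), 1, k=5)
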