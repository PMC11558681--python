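"""Frozen-structure leave-one-out influence."""

import numpy as np
import pytest

from htsval.exceptions import DegenerateInputError
from htsval.valuation.leaf_influence import LeafInfluence, _logloss


def _problem(seed, n=80, d=5, m=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
    Xt = rng.normal(size=(m, d))
    yt = (Xt[:, 0] > 0).astype(float)
    return X, y, Xt, yt


def brute_force_single_tree(li: LeafInfluence):
    """Frozen-structure retrain oracle: recompute leaf values from the
    gradient/Hessian statistics without each sample, one round."""
    _, leaf_train, leaf_target = li._train_structures()
    n = len(li.y)
    lr, lam = li.learning_rate, li.reg_lambda
    p0 = 0.5 * np.ones(n)
    g, h = p0 - li.y, p0 * (1 - p0)
    leaves, tgt = leaf_train[:, 0], leaf_target[:, 0]
    nl = int(max(leaves.max(), tgt.max())) + 1

    def values(exclude=None):
        mask = np.ones(n, bool)
        if exclude is not None:
            mask[exclude] = False
        G = np.bincount(leaves[mask], weights=g[mask], minlength=nl)
        H = np.bincount(leaves[mask], weights=h[mask], minlength=nl)
        return -lr * G / (H + lam)

    base = _logloss(values()[tgt], li.y_target).mean()
    return np.array(
        [_logloss(values(j)[tgt], li.y_target).mean() - base for j in range(n)]
    )


@pytest.mark.parametrize("seed", [0, 3, 9])
def test_single_tree_matches_brute_force_retrain(seed):
    X, y, Xt, yt = _problem(seed)
    li = LeafInfluence(
        X, y, Xt, yt, mode="test", n_rounds=1, lgbm_params={"min_child_samples": 2}
    )
    res = li.fit()
    oracle = brute_force_single_tree(li)
    assert np.abs(res.scores - oracle).max() < 1e-10


def test_disjoint_leaf_support_gives_zero_influence():
    X, y, Xt, yt = _problem(4)
    li = LeafInfluence(
        X, y, Xt, yt, mode="test", n_rounds=1, lgbm_params={"min_child_samples": 2}
    )
    res = li.fit()
    _, leaf_train, leaf_target = li._train_structures()
    outside = ~np.isin(leaf_train[:, 0], np.unique(leaf_target[:, 0]))
    assert outside.any()
    assert np.abs(res.scores[outside]).max() == 0.0


def test_duplicated_sample_influence_shrinks_with_multiplicity():
    """The more copies of a sample exist, the less removing one matters."""
    rng = np.random.default_rng(6)
    base_X = rng.normal(size=(40, 4))
    base_y = (base_X[:, 0] > 0).astype(int)
    probe = base_X[:1]
    Xt, yt = rng.normal(size=(10, 4)), (rng.random(10) > 0.5).astype(float)
    mags = []
    for m in (1, 2, 4, 8):
        X = np.vstack([base_X] + [probe] * (m - 1))
        y = np.concatenate([base_y, np.full(m - 1, base_y[0])])
        res = LeafInfluence(
            X, y, Xt, yt, mode="test", n_rounds=1,
            lgbm_params={"min_child_samples": 2},
        ).fit()
        mags.append(abs(res.scores[0]))
    assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))


def test_self_mode_targets_actives():
    X, y, _, _ = _problem(2)
    res = LeafInfluence(
        X, y, mode="self", n_rounds=5, lgbm_params={"min_child_samples": 2}
    ).fit()
    assert len(res.scores) == len(y)
    assert res.config.mode == "self"


def test_empty_target_errors():
    X, y, _, _ = _problem(1)
    with pytest.raises(DegenerateInputError):
        LeafInfluence(X, y, None, None, mode="test")
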