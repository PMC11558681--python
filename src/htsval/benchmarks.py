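"""Validation benchmarks: oracle equivalences and synthetic-screen studies.

Each function here re-runs one of the package's verification studies from
scratch — exact-oracle comparisons for the valuation engines (subset
enumeration, frozen-structure retraining, finite differences) and
synthetic-screen recovery studies for the three workflows — and returns
plain numbers.  The test suite asserts on these numbers; the
reproduction script reports them.

Problem sizes are chosen for desk-scale runtimes: the oracle checks use
tiny instances where exhaustive computation is exact, and the workflow
studies use screens of 500-5000 compounds with 10 replicate seeds.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
from lightgbm import LGBMClassifier
from scipy.stats import spearmanr, wilcoxon

from .active_learning import ALConfig, run_campaign
from .data import build_splits
from .synth import SynthConfig, generate_screen
from .triage import rank_candidates, evaluate_triage
from .undersample import UndersampleConfig, run_undersampling
from .valuation import LeafInfluence, TracInImportance, mvsa_scores
from .valuation.knn_shapley import knn_shapley_single
from .valuation.leaf_influence import _logloss

_SMALL_TREES = {"min_child_samples": 5}


# ------------------------------------------------------------------ #
# KNN-Shapley oracles


def knn_brute_force_shapley(X, y, xv, yv, k) -> np.ndarray:
    """Exhaustive subset-enumeration Shapley values of the KNN utility
    (empty-coalition utility 0)."""
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


def knn_shapley_enumeration_deviation(seed: int = 0) -> float:
    """Max |recursion - enumeration| over several tiny instances."""
    rng = np.random.default_rng(seed)
    dev = 0.0
    for n, k in ((6, 2), (7, 3), (8, 1), (8, 3)):
        X = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, n)
        xv = rng.normal(size=3)
        yv = int(rng.integers(0, 2))
        exact = knn_brute_force_shapley(X, y, xv, yv, k)
        rec = knn_shapley_single(X, y, xv, yv, k)
        dev = max(dev, float(np.abs(exact - rec).max()))
    return dev


def knn_shapley_efficiency_gap(seed: int = 0) -> float:
    """Max |sum_j s_j - v(full)| over validation points and K values."""
    rng = np.random.default_rng(seed)
    gap = 0.0
    X = rng.normal(size=(30, 4))
    y = rng.integers(0, 2, 30)
    for k in (1, 3, 5):
        for _ in range(5):
            xv = rng.normal(size=4)
            yv = int(rng.integers(0, 2))
            s = knn_shapley_single(X, y, xv, yv, k)
            dist = np.linalg.norm(X - xv, axis=1)
            order = np.lexsort((np.arange(30), dist))
            v_full = (y[order[:k]] == yv).sum() / k
            gap = max(gap, abs(float(s.sum()) - v_full))
    return gap


# ------------------------------------------------------------------ #
# Leaf-influence oracle


def leaf_influence_oracle_deviation(seed: int = 0) -> float:
    """Max |engine - brute-force frozen-structure LOO| for single trees."""
    dev = 0.0
    for off in range(3):
        rng = np.random.default_rng(seed + off)
        n, d, m = 80, 5, 12
        X = rng.normal(size=(n, d))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
        Xt = rng.normal(size=(m, d))
        yt = (Xt[:, 0] > 0).astype(float)
        li = LeafInfluence(
            X, y, Xt, yt, mode="test", n_rounds=1,
            lgbm_params={"min_child_samples": 2},
        )
        res = li.fit()

        _, leaf_train, leaf_target = li._train_structures()
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
        oracle = np.array(
            [_logloss(values(j)[tgt], li.y_target).mean() - base for j in range(n)]
        )
        dev = max(dev, float(np.abs(res.scores - oracle).max()))
    return dev


# ------------------------------------------------------------------ #
# TracIn finite-difference oracle


def tracin_fd_relative_error(seed: int = 0, eps: float = 1e-6) -> float:
    """Max relative error of single-checkpoint self-importance against
    central finite differences of the per-sample loss."""
    rng = np.random.default_rng(seed)
    n, d = 20, 8
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, n)
    ti = TracInImportance(
        X, y, mode="self", hidden=(8, 8, 8), epochs=5, checkpoint_epochs=(5,),
        batch_size=8, dropout=0.0, seed=seed,
    )
    res = ti.fit()
    net, params = ti.net_, ti.checkpoints_[0].params
    fd = np.zeros(n)
    for li in (-2, -1):
        W, b = params[li]
        for arr in (W, b):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = net.loss(X, y, params)
                arr[ix] = orig - eps
                lm = net.loss(X, y, params)
                arr[ix] = orig
                fd += ((lp - lm) / (2 * eps)) ** 2
    return float((np.abs(fd - res.scores) / np.maximum(np.abs(fd), 1e-30)).max())


# ------------------------------------------------------------------ #
# MVS-A symmetry + flipped-label recovery


def mvsa_round1_spread(seed: int = 0) -> float:
    """Spread of the first boosting round's contributions (0 = symmetric)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(60, 8))
    y = (X[:, 0] > 0).astype(int)
    res = mvsa_scores(X, y, seed=seed, n_rounds=5, lgbm_params=_SMALL_TREES)
    first = res.diagnostics["round1_contribution"]
    return float(np.ptp(first))


def mvsa_flip_recovery(
    seeds, n: int = 500, d: int = 32, with_loo: bool = True
) -> dict:
    """Flipped-label recovery on n-compound screens with 10 planted
    mislabeled actives: median rank fraction of the flipped samples and
    (optionally) Spearman correlation of MVS-A scores with exhaustive
    leave-one-out retraining loss deltas."""
    med_fracs, rhos = [], []
    for seed in seeds:
        ds, feats, truth = generate_screen(
            SynthConfig(n=n, active_rate=0.1, fp_rate=0.2, d=d, seed=seed)
        )
        X, y = feats.values, ds.primary_labels
        flipped = truth.is_fp.to_numpy()
        res = mvsa_scores(X, y, seed=seed)
        order = np.argsort(-res.scores, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        med_fracs.append(float(np.median(ranks[flipped])) / n)

        if with_loo:
            def _fit(mask):
                m = LGBMClassifier(
                    n_estimators=100, reg_lambda=1.0, colsample_bytree=0.95,
                    random_state=seed, boost_from_average=False, n_jobs=1,
                    verbose=-1, deterministic=True, force_row_wise=True,
                )
                m.fit(X[mask], y[mask])
                return m

            def _loss(model):
                p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
                return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).sum())

            base = _loss(_fit(np.ones(n, bool)))
            deltas = np.empty(n)
            for j in range(n):
                mask = np.ones(n, bool)
                mask[j] = False
                deltas[j] = _loss(_fit(mask)) - base
            rhos.append(float(spearmanr(res.scores, deltas).statistic))
    return {"median_rank_fraction": med_fracs, "loo_spearman": rhos}


# ------------------------------------------------------------------ #
# Workflow studies


def triage_fp_study(seeds, n: int = 3000, d: int = 1024) -> dict:
    """False-positive nomination with 30% planted FPs among actives:
    MVS-A nominee precision vs base rate and the structural-alert
    filter benchmark."""
    out = {"mvsa_precision": [], "base_rate": [], "filter_precision": []}
    for seed in seeds:
        ds, feats, _ = generate_screen(
            SynthConfig(n=n, active_rate=0.03, fp_rate=0.3, d=d, seed=seed)
        )
        splits = build_splits(ds, seed=seed)
        tr = splits.train_idx
        y = ds.primary_labels
        res = mvsa_scores(feats.values[tr], y[tr], seed=seed)
        ranked = rank_candidates(ds, importance=res, train_idx=tr)
        rep = evaluate_triage(ranked, ds)["fp"]
        out["mvsa_precision"].append(rep.values["precision"])
        out["base_rate"].append(rep.base_rate)
        fb = rank_candidates(ds, benchmark="filters", train_idx=tr)
        out["filter_precision"].append(
            evaluate_triage(fb, ds)["fp"].values["precision"]
        )
    return out


def active_learning_study(
    seeds, n: int = 5000, n_steps: int = 5, d: int = 1024
) -> dict:
    """Actives retrieved at the final step for each selection strategy on
    a 2%-active library, plus one-sided paired signed-rank p-values of
    greedy/importance beating random."""
    engine_params = {"engine": {"lgbm_params": _SMALL_TREES}}
    found = {s: [] for s in ("random", "greedy", "importance")}
    for seed in seeds:
        ds, feats, _ = generate_screen(
            SynthConfig(n=n, active_rate=0.02, fp_rate=0.0, d=d, seed=seed)
        )
        for strategy in found:
            cfg = ALConfig(
                n_steps=n_steps, strategy=strategy, seed=seed,
                engine_params=engine_params,
            )
            found[strategy].append(run_campaign(ds, feats, cfg).cum_actives[-1])
    out = {k: v for k, v in found.items()}
    for strategy in ("greedy", "importance"):
        stat = wilcoxon(
            found[strategy], found["random"], alternative="greater"
        )
        out[f"p_{strategy}_gt_random"] = float(stat.pvalue)
    return out


def undersampling_study(
    seeds, n: int = 1500, d: int = 128
) -> dict:
    """Average-precision curves under the three removal policies and the
    one-sided paired p-value that drop_high < random at 50% removed."""
    curves = {p: [] for p in ("drop_high", "drop_low", "random")}
    for seed in seeds:
        ds, feats, _ = generate_screen(
            SynthConfig(n=n, active_rate=0.05, fp_rate=0.2, d=d, seed=seed)
        )
        splits = build_splits(ds, seed=seed)
        for policy in curves:
            cfg = UndersampleConfig(
                policy=policy, seed=seed, engine_params={"lgbm_params": _SMALL_TREES}
            )
            curves[policy].append(
                run_undersampling(ds, feats, splits, cfg).avg_precision
            )
    arr = {p: np.array(v) for p, v in curves.items()}
    k50 = 10  # 5% steps -> step index 10 is 50% removed
    p50 = float(
        wilcoxon(arr["drop_high"][:, k50], arr["random"][:, k50],
                 alternative="less").pvalue
    )
    return {
        "curves": {p: v.tolist() for p, v in arr.items()},
        "ap_drop_high_50": float(arr["drop_high"][:, k50].mean()),
        "ap_random_50": float(arr["random"][:, k50].mean()),
        "ap_drop_low_50": float(arr["drop_low"][:, k50].mean()),
        "p_drop_high_lt_random_50": p50,
        "mean_low_ge_high_all_steps": bool(
            np.all(arr["drop_low"].mean(0) >= arr["drop_high"].mean(0))
        ),
    }
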