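"""Importance-guided undersampling of the inactive majority class.

Importance is computed once on the full training split; then, in steps
of 5% of the original training size, inactives are removed by policy —
highest-score first (``drop_high``), lowest-score first (``drop_low``),
or seeded-random — until 95% of the training set is removed or the
inactives are exhausted (flagged).  After every step a boosted-tree
classifier is retrained on the retained set and scored by average
precision on the validation split.  Actives are never removed, so the
class ratio improves monotonically under every policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier

from .data import ScreenDataset, SplitSpec
from .exceptions import ConfigError, DegenerateInputError, HtsvalError
from .features import FeatureMatrix
from .metrics import average_precision, rank_order
from .valuation import ENGINES

POLICIES = ("drop_high", "drop_low", "random")


@dataclass
class UndersampleConfig:
    step: float = 0.05
    max_removed: float = 0.95
    policy: str = "drop_high"
    engine: str = "mvsa"
    seed: int = 0
    engine_params: dict = field(default_factory=dict)
    classifier_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.step <= 0.5):
            raise ConfigError("step must lie in (0, 0.5]")
        if not (0 < self.max_removed < 1):
            raise ConfigError("max_removed must lie in (0, 1)")
        if self.policy not in POLICIES:
            raise ConfigError(f"policy must be one of {POLICIES}")


@dataclass
class UndersampleTrace:
    retained: list = field(default_factory=list)  # index arrays, nested
    frac_removed: list = field(default_factory=list)
    avg_precision: list = field(default_factory=list)
    exhausted: bool = False
    config: UndersampleConfig | None = None

    def summary(self) -> str:
        lines = [
            f"Undersampling trace: policy={self.config.policy} "
            f"engine={self.config.engine} seed={self.config.seed}",
            "  step  frac_removed  n_retained  avg_precision",
        ]
        for i, (r, f, ap) in enumerate(
            zip(self.retained, self.frac_removed, self.avg_precision)
        ):
            lines.append(f"  {i:4d}  {f:12.2f}  {len(r):10d}  {ap:13.4f}")
        if self.exhausted:
            lines.append("  inactives exhausted before max_removed")
        return "\n".join(lines)


def _val_average_precision(
    clf: LGBMClassifier, X_val: np.ndarray, y_val: np.ndarray
) -> float:
    prob = clf.predict_proba(X_val)[:, 1]
    order = rank_order(prob, descending=True)
    return average_precision(order, np.flatnonzero(y_val == 1))


def run_undersampling(
    ds: ScreenDataset,
    X: FeatureMatrix | np.ndarray,
    splits: SplitSpec,
    cfg: UndersampleConfig,
) -> UndersampleTrace:
    """Run one undersampling sweep; see module docstring.

    Ties in importance at a removal boundary are broken by ascending
    training index (stable sort).  The trace is reproducible from
    (dataset, config, seed).
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    train_idx, val_idx = np.asarray(splits.train_idx), np.asarray(splits.val_idx)
    y = ds.primary_labels
    y_train, y_val = y[train_idx], y[val_idx]
    if len(val_idx) == 0:
        raise ConfigError("validation split is empty")
    if len(np.unique(y_val)) < 2:
        raise DegenerateInputError("validation split is single-class")

    n_train = len(train_idx)
    per_step = int(round(cfg.step * n_train))
    inactive_pos = np.flatnonzero(y_train == 0)  # positions within train_idx
    if len(inactive_pos) < per_step:
        raise ConfigError("training split has fewer inactives than one step")

    if cfg.policy == "random":
        rng = np.random.default_rng(cfg.seed)
        removal_order = rng.permutation(inactive_pos)
    else:
        engine_cls = ENGINES[cfg.engine]
        try:
            res = engine_cls(
                Xv[train_idx], y_train, seed=cfg.seed, **cfg.engine_params
            ).fit()
        except HtsvalError as exc:
            raise HtsvalError(f"undersampling: engine scores not computable: {exc}")
        scores = res.scores[inactive_pos]
        descending = cfg.policy == "drop_high"
        order = np.argsort(-scores if descending else scores, kind="stable")
        removal_order = inactive_pos[order]

    clf_params = dict(random_state=cfg.seed, n_jobs=1, verbose=-1)
    clf_params.update(cfg.classifier_params)

    trace = UndersampleTrace(config=cfg)
    retained_mask = np.ones(n_train, dtype=bool)

    def _score_step(frac: float) -> None:
        keep = train_idx[retained_mask]
        clf = LGBMClassifier(**clf_params)
        clf.fit(Xv[keep], y[keep])
        trace.retained.append(keep)
        trace.frac_removed.append(frac)
        trace.avg_precision.append(
            _val_average_precision(clf, Xv[val_idx], y_val)
        )

    _score_step(0.0)
    n_removed = 0
    while True:
        target = n_removed + per_step
        if target > cfg.max_removed * n_train + 1e-9:
            break
        if target > len(removal_order):
            trace.exhausted = True
            break
        retained_mask[removal_order[n_removed:target]] = False
        n_removed = target
        _score_step(n_removed / n_train)
    return trace
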