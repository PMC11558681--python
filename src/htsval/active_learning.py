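"""Iterative compound-library screening (active learning).

A campaign starts from a stratified random batch of 1.5% of the library
and repeatedly selects equally sized batches of unscreened compounds:

* ``random`` — seeded shuffle of the remainder, take the prefix;
* ``greedy`` — a boosted-tree classifier fit on the screened compounds
  ranks the remainder by predicted active probability;
* ``importance`` — a valuation engine (default MVS-A) scores the
  screened compounds, a regressor (default Gaussian process) is fit
  features -> importance, and the remainder is ranked by predicted
  importance.

Primary-screen labels are revealed for each selected batch; the trace
records cumulative active retrieval per step.  Batch size is a fixed
fraction of the *full* library size, recomputed as ``round(f * n)``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF

from .data import ScreenDataset, stratified_indices
from .exceptions import ConfigError, DegenerateInputError, HtsvalError
from .features import FeatureMatrix
from .valuation import ENGINES

logger = logging.getLogger(__name__)


@dataclass
class ALConfig:
    """Campaign configuration (fractions are of the full library)."""

    n_steps: int
    step_fraction: float = 0.015
    strategy: str = "importance"
    engine: str = "mvsa"
    regressor: str = "gaussian_process"
    seed: int = 0
    engine_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.step_fraction < 0.5):
            raise ConfigError("step_fraction must lie in (0, 0.5)")
        if self.n_steps * self.step_fraction > 1 + 1e-9:
            raise ConfigError("n_steps * step_fraction must not exceed 1")
        if self.strategy not in ("random", "greedy", "importance"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.regressor not in ("gaussian_process", "boosted_trees"):
            raise ConfigError(f"unknown regressor {self.regressor!r}")


@dataclass
class CampaignTrace:
    """Per-step selections and cumulative active retrieval."""

    step_idx: list = field(default_factory=list)  # list of index arrays
    cum_actives: list = field(default_factory=list)
    cum_fraction: list = field(default_factory=list)
    wall_time: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    config: ALConfig | None = None

    @property
    def screened(self) -> np.ndarray:
        return np.concatenate(self.step_idx) if self.step_idx else np.array([], int)

    def summary(self) -> str:
        lines = [
            f"Active-learning campaign: strategy={self.config.strategy} "
            f"seed={self.config.seed}",
            "  step  n_selected  cum_actives  cum_fraction",
        ]
        for i, (idx, ca, cf) in enumerate(
            zip(self.step_idx, self.cum_actives, self.cum_fraction)
        ):
            lines.append(f"  {i:4d}  {len(idx):10d}  {ca:11d}  {cf:12.3f}")
        if self.flags:
            lines.append(f"  flags: {self.flags}")
        return "\n".join(lines)


def _fit_gpr(X: np.ndarray, y: np.ndarray, seed: int) -> GaussianProcessRegressor:
    # median-heuristic length scale, fixed (not optimised) for determinism
    n = len(X)
    rng = np.random.default_rng([seed, 331])
    sub = X[rng.choice(n, size=min(n, 200), replace=False)]
    d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
    med = np.median(d[np.triu_indices_from(d, k=1)])
    ls = float(med) if med > 0 else 1.0
    gpr = GaussianProcessRegressor(
        kernel=RBF(length_scale=ls),
        alpha=1e-6,
        optimizer=None,
        normalize_y=True,
        random_state=seed,
    )
    gpr.fit(X, y)
    return gpr


def select_batch(
    labeled_idx: np.ndarray,
    remainder_idx: np.ndarray,
    X: np.ndarray,
    y_labeled: np.ndarray,
    batch_size: int,
    cfg: ALConfig,
    step: int,
) -> tuple[np.ndarray, list[str]]:
    """Select the next batch of unscreened compounds under a strategy.

    Returns the selected indices (into the library) and any flags raised
    (truncation, fallback to random).  Deterministic given
    (inputs, config, seed, step).
    """
    if len(remainder_idx) == 0:
        raise ConfigError("remainder is empty")
    flags: list[str] = []
    if len(remainder_idx) <= batch_size:
        flags.append(f"step {step}: truncated final batch ({len(remainder_idx)})")
        return np.sort(remainder_idx), flags

    strategy = cfg.strategy
    if strategy != "random" and len(np.unique(y_labeled)) < 2:
        flags.append(f"step {step}: single-class labeled set, falling back to random")
        strategy = "random"

    if strategy == "random":
        rng = np.random.default_rng([cfg.seed, step])
        picked = rng.permutation(remainder_idx)[:batch_size]
        return np.sort(picked), flags

    if strategy == "greedy":
        clf = LGBMClassifier(random_state=cfg.seed, n_jobs=1, verbose=-1,
                             **cfg.engine_params.get("classifier", {}))
        clf.fit(X[labeled_idx], y_labeled)
        prob = clf.predict_proba(X[remainder_idx])[:, 1]
        order = np.argsort(-prob, kind="stable")
        return np.sort(remainder_idx[order[:batch_size]]), flags

    # importance strategy
    engine_cls = ENGINES[cfg.engine]
    if cfg.engine != "mvsa":
        raise ConfigError(
            "importance strategy currently drives self-importance engines; "
            f"{cfg.engine!r} is not supported here"
        )
    try:
        res = engine_cls(
            X[labeled_idx], y_labeled, seed=cfg.seed,
            **cfg.engine_params.get("engine", {}),
        ).fit()
    except HtsvalError as exc:
        raise HtsvalError(f"step {step}, strategy importance: engine failed: {exc}")
    try:
        if cfg.regressor == "gaussian_process":
            reg = _fit_gpr(X[labeled_idx], res.scores, cfg.seed)
        else:
            reg = LGBMRegressor(random_state=cfg.seed, n_jobs=1, verbose=-1)
            reg.fit(X[labeled_idx], res.scores)
        pred = reg.predict(X[remainder_idx])
    except Exception as exc:  # regressor failure names step and strategy
        raise HtsvalError(
            f"step {step}, strategy importance: regressor fit failed: {exc}"
        ) from exc
    order = np.argsort(-pred, kind="stable")
    return np.sort(remainder_idx[order[:batch_size]]), flags


def run_campaign(
    ds: ScreenDataset, X: FeatureMatrix | np.ndarray, cfg: ALConfig
) -> CampaignTrace:
    """Run a full screening campaign; see module docstring.

    Step 0 is the stratified initialisation batch; steps 1..n_steps are
    strategy selections.  The trace is bitwise reproducible from
    (dataset, config, seed).
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    y = ds.primary_labels
    n = len(ds)
    if Xv.shape[0] != n:
        raise ConfigError("feature matrix is not aligned with the dataset")
    if y.sum() < 1:
        raise DegenerateInputError("dataset has no actives")

    batch = int(round(cfg.step_fraction * n))
    if batch < 1:
        raise ConfigError("step_fraction * n rounds to zero")
    n_actives_total = int(y.sum())

    trace = CampaignTrace(config=cfg)
    init = stratified_indices(y, np.arange(n), batch, cfg.seed)
    screened = np.zeros(n, dtype=bool)

    def _record(idx: np.ndarray) -> None:
        screened[idx] = True
        found = int(y[screened].sum())
        trace.step_idx.append(idx)
        trace.cum_actives.append(found)
        trace.cum_fraction.append(found / n_actives_total)

    t0 = time.perf_counter()
    _record(init)
    trace.wall_time.append(time.perf_counter() - t0)

    for step in range(1, cfg.n_steps + 1):
        t0 = time.perf_counter()
        remainder = np.flatnonzero(~screened)
        if len(remainder) == 0:
            trace.flags.append(f"step {step}: library exhausted")
            break
        labeled = np.flatnonzero(screened)
        idx, flags = select_batch(labeled, remainder, Xv, y[labeled], batch, cfg, step)
        trace.flags.extend(flags)
        _record(idx)
        trace.wall_time.append(time.perf_counter() - t0)
        for f in flags:
            logger.info("%s", f)
    return trace
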