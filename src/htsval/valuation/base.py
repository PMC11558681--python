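"""Shared model/results scaffolding for the valuation engines."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import DegenerateInputError


@dataclass
class ValuationConfig:
    """Engine identity + mode + seed + engine-specific parameters."""

    engine: str
    mode: str = "self"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "mode": self.mode,
            "seed": self.seed,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
        }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    return v


class ImportanceResults:
    """Per-training-compound importance scores from one engine run.

    Attributes
    ----------
    scores : ndarray, shape (n_train,)
        Finite importance values, aligned with the training rows.
    config : ValuationConfig
    diagnostics : dict
        Engine-specific extras (flags, per-checkpoint pieces, ...).
    model_fingerprint : str
        Hash of the trained backing model's parameters, for provenance.
    """

    def __init__(
        self,
        scores: np.ndarray,
        config: ValuationConfig,
        diagnostics: dict | None = None,
        model_fingerprint: str = "",
    ) -> None:
        scores = np.asarray(scores, dtype=np.float64)
        if not np.all(np.isfinite(scores)):
            raise DegenerateInputError("importance scores contain non-finite values")
        self.scores = scores
        self.config = config
        self.diagnostics = diagnostics or {}
        self.model_fingerprint = model_fingerprint

    def __len__(self) -> int:
        return len(self.scores)

    def rank_order(self, descending: bool = True) -> np.ndarray:
        key = -self.scores if descending else self.scores
        return np.argsort(key, kind="stable")

    def to_frame(self, compound_ids=None) -> pd.DataFrame:
        ids = (
            list(compound_ids)
            if compound_ids is not None
            else [str(i) for i in range(len(self.scores))]
        )
        return pd.DataFrame(
            {
                "compound_id": ids,
                "engine": self.config.engine,
                "mode": self.config.mode,
                "seed": self.config.seed,
                "score": self.scores,
            }
        )

    def to_csv(self, path, compound_ids=None) -> None:
        self.to_frame(compound_ids).to_csv(path, index=False)

    def config_json(self) -> str:
        return json.dumps(self.config.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        s = self.scores
        top = np.argsort(-s, kind="stable")[:5]
        lines = [
            f"Importance results: engine={self.config.engine} "
            f"mode={self.config.mode} seed={self.config.seed}",
            f"  n_train={len(s)}  min={s.min():.6g}  median={np.median(s):.6g}  "
            f"max={s.max():.6g}",
            f"  top-5 training indices by score: {top.tolist()}",
        ]
        if self.model_fingerprint:
            lines.append(f"  model fingerprint: {self.model_fingerprint[:16]}")
        for k, v in self.diagnostics.items():
            if np.isscalar(v):
                lines.append(f"  {k}: {v}")
        return "\n".join(lines)


def fingerprint_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
    return h.hexdigest()


def check_binary_labels(y: np.ndarray, who: str) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateInputError(f"{who}: labels contain a single class")
    if not set(classes.tolist()) <= {0, 1}:
        raise DegenerateInputError(f"{who}: labels must be binary 0/1")
    return y.astype(np.int64)
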