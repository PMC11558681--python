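"""Synthetic screen generator.

Emulates the statistical structure of a curated primary + confirmatory
HTS table without any chemistry on the critical path:

* latent structural clusters — binary prototype vectors in {0,1}^d;
  compounds are prototypes with independent bit flips (``bit_noise``);
* strong class imbalance — a small ``active_rate``;
* two-tier labels — every primary active carries a confirmatory call;
* planted false positives — a fraction ``fp_rate`` of the primary
  actives are *structurally isolated* compounds (independent random bit
  vectors far from every active prototype) whose confirmatory label is
  0: they mimic assay artifacts that look nothing like the true actives;
* activity scores correlated with the labels — Gaussian signal + noise
  clipped to [0, 100], with false-positive scores overlapping
  true-positive scores.

Ground truth (cluster id, is_fp) is returned separately and never
leaks into the dataset columns.  SMILES from the embedded fixture list
are attached (cycled) so filter-based benchmarks and I/O round-trips
are exercisable; they carry no relation to the feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._smiles_fixtures import fixture_smiles
from .data import ScreenDataset
from .exceptions import ConfigError
from .features import FeatureMatrix


@dataclass
class SynthConfig:
    n: int = 2000
    active_rate: float = 0.02
    fp_rate: float = 0.3
    n_clusters: int = 10
    n_active_clusters: int = 2
    d: int = 1024
    bit_density: float = 0.1
    bit_noise: float = 0.05
    score_noise: float = 15.0
    active_score_mean: float = 60.0
    inactive_score_mean: float = 40.0
    attach_smiles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.active_rate < 0.5):
            raise ConfigError("active_rate must lie in (0, 0.5)")
        if not (0 <= self.fp_rate < 1):
            raise ConfigError("fp_rate must lie in [0, 1)")
        if self.d < 16:
            raise ConfigError("d must be >= 16")
        if int(round(self.n * self.active_rate)) < 2:
            raise ConfigError("n * active_rate must be >= 2")
        if self.n_active_clusters >= self.n_clusters:
            raise ConfigError("need at least one background cluster")


def generate_screen(
    cfg: SynthConfig,
) -> tuple[ScreenDataset, FeatureMatrix, pd.DataFrame]:
    """Generate a synthetic screen; bitwise deterministic from the seed.

    Returns
    -------
    (dataset, features, truth)
        ``dataset`` holds exactly ``round(n * active_rate)`` primary
        actives, of which ``round(fp_rate * n_actives)`` are planted
        false positives (confirmatory 0) and the rest true actives
        (confirmatory 1).  ``features`` is the n x d binary matrix the
        compounds were generated from.  ``truth`` has columns
        ``cluster_id`` (-1 for planted FPs) and ``is_fp``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_act = int(round(cfg.n * cfg.active_rate))
    n_fp = int(round(cfg.fp_rate * n_act))
    n_true = n_act - n_fp
    n_inact = cfg.n - n_act

    protos = (rng.random((cfg.n_clusters, cfg.d)) < cfg.bit_density).astype(np.float64)
    active_protos = np.arange(cfg.n_active_clusters)
    bg_protos = np.arange(cfg.n_active_clusters, cfg.n_clusters)

    def _around(proto_ids: np.ndarray) -> np.ndarray:
        base = protos[proto_ids]
        flips = rng.random(base.shape) < cfg.bit_noise
        return np.abs(base - flips.astype(np.float64))

    true_clusters = rng.choice(active_protos, size=n_true)
    inact_clusters = rng.choice(bg_protos, size=n_inact)
    X_true = _around(true_clusters)
    X_inact = _around(inact_clusters)
    # planted FPs: isolated random bit vectors, unrelated to any prototype
    X_fp = (rng.random((n_fp, cfg.d)) < cfg.bit_density).astype(np.float64)

    X = np.vstack([X_true, X_fp, X_inact])
    primary = np.concatenate(
        [np.ones(n_true + n_fp, dtype=np.int64), np.zeros(n_inact, dtype=np.int64)]
    )
    confirmatory = np.concatenate(
        [np.ones(n_true), np.zeros(n_fp), np.full(n_inact, np.nan)]
    )
    cluster_id = np.concatenate(
        [true_clusters, np.full(n_fp, -1, dtype=np.int64), inact_clusters]
    )
    is_fp = np.concatenate(
        [np.zeros(n_true, bool), np.ones(n_fp, bool), np.zeros(n_inact, bool)]
    )

    means = np.where(primary == 1, cfg.active_score_mean, cfg.inactive_score_mean)
    scores = np.clip(means + rng.normal(0, cfg.score_noise, cfg.n), 0.0, 100.0)

    perm = rng.permutation(cfg.n)
    X, primary, confirmatory = X[perm], primary[perm], confirmatory[perm]
    cluster_id, is_fp, scores = cluster_id[perm], is_fp[perm], scores[perm]

    if cfg.attach_smiles:
        pool = fixture_smiles()
        smiles = [pool[i % len(pool)] for i in range(cfg.n)]
    else:
        smiles = ["*"] * cfg.n

    frame = pd.DataFrame(
        {
            "compound_id": [f"syn_{i:06d}" for i in range(cfg.n)],
            "smiles": smiles,
            "activity_score": scores,
            "primary_label": primary,
            "confirmatory_label": confirmatory,
        }
    )
    ds = ScreenDataset(frame, name=f"synthetic_seed{cfg.seed}", meta={"synthetic": True})
    features = FeatureMatrix(X, "fingerprint", {"synthetic": True, "d": cfg.d})
    truth = pd.DataFrame({"cluster_id": cluster_id, "is_fp": is_fp})
    return ds, features, truth
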