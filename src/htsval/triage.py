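"""False/true-positive triage of primary-screen actives.

Primary actives are ranked by an importance vector (or a benchmark) and
the extreme deciles nominated: for *self-importance* engines (MVS-A,
TracIn self, leaf-influence self) the highest scores are false-positive
nominees and the lowest true-positive nominees; for *test-importance*
engines (KNN-Shapley, leaf-influence test, DVRL, TracIn test/pos) the
polarity is reversed.  The orientation table is data
(:data:`DEFAULT_ORIENTATION`), so new engines declare their polarity
explicitly.

Benchmarks: ``filters`` ranks actives by the number of matched
structural alerts (GSK hard-filter catalog plus the REOS property
rules); ``score`` ranks by primary activity score (highest = most
TP-like); ``random`` is a seeded shuffle.

Evaluation is restricted to confirmatory-labeled actives: the FP task
treats confirmatory = 0 as positive, the TP task confirmatory = 1.
Reported metrics: precision over the nominated decile, relative
precision (precision minus the task base rate), enrichment factor at
10%, and BEDROC (alpha = 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, FilterCatalog, Lipinski

from .data import ScreenDataset
from .exceptions import ConfigError, DegenerateInputError
from .metrics import (
    MetricConfig,
    MetricReport,
    bedroc_from_order,
    enrichment_factor,
    precision_at,
)
from .valuation.base import ImportanceResults

#: (engine, mode) -> "fp_high" (high score = FP nominee) or "tp_high"
DEFAULT_ORIENTATION = {
    ("mvsa", "self"): "fp_high",
    ("tracin", "self"): "fp_high",
    ("leaf_influence", "self"): "fp_high",
    ("knn_shapley", "test"): "tp_high",
    ("leaf_influence", "test"): "tp_high",
    ("dvrl", "test"): "tp_high",
    ("tracin", "test"): "tp_high",
    ("tracin", "pos"): "tp_high",
}

ALERT_CATALOG_VERSION = "RDKit FilterCatalog CHEMBL_Glaxo + REOS property rules"


@dataclass
class TriageConfig:
    decile_fraction: float = 0.10
    orientation: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    metric: MetricConfig = field(default_factory=MetricConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.decile_fraction < 0.5):
            raise ConfigError("decile_fraction must lie in (0, 0.5)")


@dataclass
class TriageResult:
    """Ranked actives plus FP/TP nominee sets.

    ``fp_order`` lists active indices from most to least FP-like;
    ``tp_order`` is the reverse.  Indices refer to dataset records.
    """

    active_idx: np.ndarray
    fp_order: np.ndarray
    scores: np.ndarray  # aligned with active_idx
    fp_nominees: np.ndarray
    tp_nominees: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def tp_order(self) -> np.ndarray:
        return self.fp_order[::-1]


# --------------------------------------------------------------------- #
# structural-alert benchmark

_REOS_RULES = (
    ("MolWt", lambda m: Descriptors.MolWt(m), 200, 500),
    ("LogP", lambda m: Crippen.MolLogP(m), -5, 5),
    ("HBD", lambda m: Lipinski.NumHDonors(m), 0, 5),
    ("HBA", lambda m: Lipinski.NumHAcceptors(m), 0, 10),
    ("FormalCharge", lambda m: Chem.GetFormalCharge(m), -2, 2),
    ("RotatableBonds", lambda m: Lipinski.NumRotatableBonds(m), 0, 8),
    ("HeavyAtoms", lambda m: m.GetNumHeavyAtoms(), 15, 50),
)


@lru_cache(maxsize=1)
def _gsk_catalog() -> FilterCatalog.FilterCatalog:
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.CHEMBL_Glaxo)
    return FilterCatalog.FilterCatalog(params)


@lru_cache(maxsize=100_000)
def alert_count(smiles: str) -> int:
    """Matched GSK structural alerts + violated REOS property rules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return 0
    n = len(_gsk_catalog().GetMatches(mol))
    for _, fn, lo, hi in _REOS_RULES:
        v = fn(mol)
        if not (lo <= v <= hi):
            n += 1
    return n


def alert_counts(smiles_list) -> np.ndarray:
    return np.array([alert_count(s) for s in smiles_list], dtype=np.float64)


# --------------------------------------------------------------------- #


def _nominee_size(n_actives: int, fraction: float) -> int:
    return max(1, int(round(fraction * n_actives)))


def rank_candidates(
    ds: ScreenDataset,
    importance: ImportanceResults | None = None,
    cfg: TriageConfig | None = None,
    benchmark: str | None = None,
    train_idx: np.ndarray | None = None,
) -> TriageResult:
    """Rank primary actives and nominate FP/TP deciles.

    Either ``importance`` (covering the training rows; ``train_idx``
    maps its positions to dataset records, identity by default) or a
    ``benchmark`` in {"filters", "score", "random"} must be given.
    """
    cfg = cfg or TriageConfig()
    train_idx = (
        np.asarray(train_idx) if train_idx is not None else np.arange(len(ds))
    )
    y = ds.primary_labels
    active_mask = y[train_idx] == 1
    active_idx = train_idx[active_mask]
    if len(active_idx) == 0:
        raise DegenerateInputError("no primary actives to triage")

    if importance is not None:
        if len(importance.scores) != len(train_idx):
            raise ConfigError(
                "importance vector does not cover the training set "
                f"({len(importance.scores)} vs {len(train_idx)})"
            )
        key = (importance.config.engine, importance.config.mode)
        if key not in cfg.orientation:
            raise ConfigError(f"no orientation declared for engine/mode {key}")
        scores = importance.scores[active_mask]
        # fp_order: most FP-like first
        if cfg.orientation[key] == "fp_high":
            order = np.argsort(-scores, kind="stable")
        else:
            order = np.argsort(scores, kind="stable")
        method = f"{key[0]}:{key[1]}"
        meta = {"orientation": cfg.orientation[key]}
    elif benchmark == "filters":
        scores = alert_counts([ds.smiles[i] for i in active_idx])
        order = np.argsort(-scores, kind="stable")  # more alerts = more FP-like
        method, meta = "filters", {"catalog": ALERT_CATALOG_VERSION}
    elif benchmark == "score":
        scores = ds.activity_scores[active_idx]
        order = np.argsort(scores, kind="stable")  # lowest score = most FP-like
        method, meta = "score", {}
    elif benchmark == "random":
        rng = np.random.default_rng(cfg.seed)
        scores = rng.random(len(active_idx))
        order = np.argsort(scores, kind="stable")
        method, meta = "random", {"seed": cfg.seed}
    else:
        raise ConfigError(
            "provide an importance vector or benchmark in {'filters','score','random'}"
        )

    fp_order = active_idx[order]
    k = _nominee_size(len(active_idx), cfg.decile_fraction)
    k = min(k, len(active_idx) // 2) or 1  # keep FP/TP sets disjoint
    return TriageResult(
        active_idx=active_idx,
        fp_order=fp_order,
        scores=scores[order],
        fp_nominees=fp_order[:k],
        tp_nominees=fp_order[::-1][:k],
        method=method,
        meta=meta,
    )


def evaluate_triage(
    result: TriageResult, ds: ScreenDataset, cfg: TriageConfig | None = None
) -> dict[str, MetricReport]:
    """Evaluate FP and TP nomination against confirmatory labels.

    Actives without a confirmatory label are skipped for the metrics
    (they still occupied nominee slots).  Returns one report per task
    with precision, relative precision, EF@fraction, and BEDROC.
    """
    cfg = cfg or TriageConfig()
    conf = ds.confirmatory_labels
    labeled_mask = ~np.isnan(conf[result.fp_order])
    labeled_order = result.fp_order[labeled_mask]
    if len(labeled_order) == 0:
        raise DegenerateInputError("no confirmatory-labeled actives")

    reports: dict[str, MetricReport] = {}
    for task in ("fp", "tp"):
        order = labeled_order if task == "fp" else labeled_order[::-1]
        labels = conf[order]
        target = 0.0 if task == "fp" else 1.0
        positives = np.flatnonzero(labels == target)
        base = len(positives) / len(order)
        report = MetricReport(base_rate=base)
        if base in (0.0, 1.0):
            report.degenerate = True
            report.values = {"precision": base, "relative_precision": 0.0}
            reports[task] = report
            continue
        # rank positions of positives within the labeled ordering
        local = np.arange(len(order))
        prec, rel = precision_at(local, positives, cfg.decile_fraction)
        report.values["precision"] = prec
        report.values["relative_precision"] = rel
        report.values["ef"] = enrichment_factor(
            local, positives, cfg.metric.ef_fraction
        )
        report.values["bedroc"] = bedroc_from_order(
            local, positives, cfg.metric.alpha_bedroc
        )
        reports[task] = report
    return reports


def fp_nominee_diversity(result: TriageResult, features: np.ndarray) -> float:
    """Mean pairwise Tanimoto similarity within the FP nominee set
    (binary feature rows); a structural-diversity readout, lower = more
    diverse."""
    rows = features[result.fp_nominees]
    k = len(rows)
    if k < 2:
        return 1.0
    inter = rows @ rows.T
    counts = rows.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    iu = np.triu_indices(k, k=1)
    return float(sim[iu].mean())
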