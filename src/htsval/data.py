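"""Screen-table I/O, standardization, and splits.

The canonical in-memory object is :class:`ScreenDataset`, a thin wrapper
around a pandas DataFrame with one row per compound:

``compound_id`` (str), ``smiles`` (str), ``activity_score`` (float in
[0, 100]), ``primary_label`` (0/1), ``confirmatory_label`` (0/1/NaN; only
primary actives may carry a confirmatory call).

Splits are exchanged as 0-based index arrays into the record order, never
as record copies.  The validation split is the fraction of compounds with
the highest primary activity scores; active-learning initialisation is a
stratified random subset preserving the active:inactive ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .exceptions import (
    ConfigError,
    EmptyDatasetError,
    SchemaError,
    StratificationError,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: default CSV column names; remap via ``column_map`` in :func:`load_screen_csv`
DEFAULT_COLUMNS = {
    "smiles": "smiles",
    "score": "score",
    "primary": "primary",
    "confirmatory": "confirmatory",
    "compound_id": "compound_id",
}

_CANONICAL_FIELDS = [
    "compound_id",
    "smiles",
    "activity_score",
    "primary_label",
    "confirmatory_label",
]


@dataclass
class ScreenDataset:
    """Ordered compound records plus dataset metadata.

    Parameters
    ----------
    frame
        DataFrame with the canonical columns (see module docstring).
    name
        Dataset label used in reports and output file names.
    meta
        Free-form provenance (drop/merge reports, normalization flags...).
    """

    frame: pd.DataFrame
    name: str = "screen"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _CANONICAL_FIELDS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def primary_labels(self) -> np.ndarray:
        return self.frame["primary_label"].to_numpy(dtype=np.int64)

    @property
    def activity_scores(self) -> np.ndarray:
        return self.frame["activity_score"].to_numpy(dtype=np.float64)

    @property
    def confirmatory_labels(self) -> np.ndarray:
        """Float array; NaN where no confirmatory call exists."""
        return self.frame["confirmatory_label"].to_numpy(dtype=np.float64)

    @property
    def smiles(self) -> list[str]:
        return self.frame["smiles"].tolist()

    @property
    def n_actives(self) -> int:
        return int(self.primary_labels.sum())

    @property
    def n_inactives(self) -> int:
        return self.n - self.n_actives

    def to_csv(self, path) -> None:
        out = self.frame.rename(
            columns={
                "activity_score": "score",
                "primary_label": "primary",
                "confirmatory_label": "confirmatory",
            }
        )
        out.to_csv(path, index=False)


@dataclass
class SplitSpec:
    """Validation + active-learning-initialisation split specification.

    ``val_idx`` holds the ``round(val_fraction * n)`` records with the
    highest activity scores (ties broken by ascending record index);
    ``init_idx`` is a stratified random subset of the training records.
    Resolved index arrays are filled in by :func:`build_splits`.
    """

    val_fraction: float = 0.10
    init_fraction: float = 0.015
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    init_idx: np.ndarray | None = None


def load_screen_csv(
    path,
    column_map: dict | None = None,
    name: str | None = None,
) -> ScreenDataset:
    """Read a screen CSV into a :class:`ScreenDataset`.

    Rows whose SMILES cannot be parsed or whose score is non-numeric are
    dropped; counts and reasons go to ``dataset.meta["load_report"]``.
    Scores outside [0, 100] trigger a per-dataset min-max rescale to
    [0, 100] (recorded in the report).

    Raises
    ------
    SchemaError
        If a mandatory mapped column is absent.
    EmptyDatasetError
        If no parseable rows remain.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    raw = pd.read_csv(path)
    for key in ("smiles", "score", "primary"):
        if cols[key] not in raw.columns:
            raise SchemaError(
                f"mandatory column {cols[key]!r} (role {key!r}) not in {list(raw.columns)}"
            )

    has_conf = cols["confirmatory"] in raw.columns
    has_id = cols["compound_id"] in raw.columns

    report = {"n_rows": len(raw), "n_dropped": 0, "reasons": {}}

    def _drop(reason: str, mask: pd.Series) -> pd.Series:
        k = int(mask.sum())
        if k:
            report["n_dropped"] += k
            report["reasons"][reason] = report["reasons"].get(reason, 0) + k
        return ~mask

    score = pd.to_numeric(raw[cols["score"]], errors="coerce")
    keep = _drop("non_numeric_score", score.isna())
    smiles = raw[cols["smiles"]].astype(str)
    parseable = smiles.map(lambda s: Chem.MolFromSmiles(s) is not None)
    keep &= _drop("unparsable_smiles", ~parseable & keep)

    frame = pd.DataFrame(
        {
            "compound_id": (
                raw[cols["compound_id"]].astype(str)
                if has_id
                else pd.Series([f"cpd_{i}" for i in range(len(raw))])
            ),
            "smiles": smiles,
            "activity_score": score,
            "primary_label": pd.to_numeric(raw[cols["primary"]], errors="coerce"),
            "confirmatory_label": (
                pd.to_numeric(raw[cols["confirmatory"]], errors="coerce")
                if has_conf
                else np.nan
            ),
        }
    )[keep].reset_index(drop=True)

    if len(frame) == 0:
        raise EmptyDatasetError(f"no parseable rows in {path}")

    s = frame["activity_score"]
    if s.min() < 0 or s.max() > 100:
        lo, hi = float(s.min()), float(s.max())
        frame["activity_score"] = (
            (s - lo) / (hi - lo) * 100.0 if hi > lo else 50.0
        )
        report["score_rescaled_from"] = [lo, hi]

    frame["primary_label"] = frame["primary_label"].astype(np.int64)
    # a confirmatory call on a primary inactive is dropped as inconsistent
    bad_conf = frame["confirmatory_label"].notna() & (frame["primary_label"] == 0)
    if bad_conf.any():
        report["reasons"]["confirmatory_on_inactive_cleared"] = int(bad_conf.sum())
        frame.loc[bad_conf, "confirmatory_label"] = np.nan

    ds_name = name or str(getattr(path, "stem", path))
    ds = ScreenDataset(frame, name=ds_name, meta={"load_report": report})
    logger.info("loaded %s: %d records, %d dropped", ds_name, len(frame), report["n_dropped"])
    return ds


def standardize_records(ds: ScreenDataset) -> ScreenDataset:
    """Canonicalize SMILES and deduplicate on the canonical form.

    Each structure is sanitized and rewritten as its RDKit canonical
    SMILES.  Records whose canonical forms collide are merged keeping the
    first occurrence; labels aggregate by max (active wins), the activity
    score by max.  Unsanitizable structures are dropped with a logged
    reason.  The operation is idempotent.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot standardize an empty dataset")

    canon: list[str | None] = []
    for smi in ds.frame["smiles"]:
        mol = Chem.MolFromSmiles(smi)
        canon.append(Chem.MolToSmiles(mol) if mol is not None else None)

    frame = ds.frame.copy()
    frame["smiles"] = canon
    n_failed = int(frame["smiles"].isna().sum())
    frame = frame[frame["smiles"].notna()]

    merged = (
        frame.groupby("smiles", sort=False)
        .agg(
            compound_id=("compound_id", "first"),
            activity_score=("activity_score", "max"),
            primary_label=("primary_label", "max"),
            confirmatory_label=("confirmatory_label", "max"),
        )
        .reset_index()
    )[_CANONICAL_FIELDS]

    n_merged = len(frame) - len(merged)
    meta = dict(ds.meta)
    meta["standardize_report"] = {"n_failed": n_failed, "n_merged": n_merged}
    if n_failed or n_merged:
        logger.info(
            "standardize %s: %d unsanitizable dropped, %d duplicates merged",
            ds.name, n_failed, n_merged,
        )
    return ScreenDataset(merged.reset_index(drop=True), name=ds.name, meta=meta)


def stratified_indices(
    labels: np.ndarray,
    pool: np.ndarray,
    n_pick: int,
    seed: int,
) -> np.ndarray:
    """Seeded stratified sample of ``n_pick`` indices from ``pool``,
    preserving the pool's active:inactive ratio (active count rounded)."""
    pool = np.asarray(pool)
    y = labels[pool]
    actives = pool[y == 1]
    inactives = pool[y == 0]
    if len(actives) == 0:
        raise StratificationError("no actives in the sampling pool")
    n_act = int(round(n_pick * len(actives) / len(pool)))
    n_act = min(max(n_act, 1), len(actives), n_pick)
    n_inact = min(n_pick - n_act, len(inactives))
    rng = np.random.default_rng(seed)
    picked = np.concatenate(
        [
            rng.choice(actives, size=n_act, replace=False),
            rng.choice(inactives, size=n_inact, replace=False),
        ]
    )
    return np.sort(picked)


def build_splits(ds: ScreenDataset, spec: SplitSpec | None = None, seed: int = 0) -> SplitSpec:
    """Resolve the validation and initialisation splits for a dataset.

    Validation = the ``round(val_fraction * n)`` records with the highest
    activity scores (ties by ascending record index).  The initialisation
    subset (used by active learning) is a stratified random
    ``round(init_fraction * n)``-sized sample of the *training* records,
    reproducible from ``seed``.
    """
    spec = spec or SplitSpec()
    if not (0 < spec.val_fraction < 1) or not (0 < spec.init_fraction < 1):
        raise ConfigError("val_fraction and init_fraction must lie in (0, 1)")
    n = len(ds)
    if n < 20:
        raise ConfigError(f"dataset too small to split (n={n} < 20)")
    if ds.n_actives < 1:
        raise StratificationError("dataset has no actives")

    n_val = int(round(spec.val_fraction * n))
    scores = ds.activity_scores
    # stable sort on (-score, index): ties broken by ascending record index
    order = np.lexsort((np.arange(n), -scores))
    val_idx = np.sort(order[:n_val])
    train_mask = np.ones(n, dtype=bool)
    train_mask[val_idx] = False
    train_idx = np.flatnonzero(train_mask)

    n_init = int(round(spec.init_fraction * n))
    init_idx = stratified_indices(ds.primary_labels, train_idx, n_init, seed)

    return SplitSpec(
        val_fraction=spec.val_fraction,
        init_fraction=spec.init_fraction,
        train_idx=train_idx,
        val_idx=val_idx,
        init_idx=init_idx,
    )
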