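"""Molecular feature matrices: Morgan fingerprints and RDKit descriptors.

Two representations are supported, both row-aligned with the dataset:

* ``fingerprint`` — folded binary Morgan (ECFP-like) fingerprints,
  radius 2, 1024 bits by default.
* ``descriptor`` — a pinned list of 208 RDKit physicochemical descriptors
  (the full ``Descriptors.descList`` minus the overflow-prone
  information-content pair ``Ipc``/``AvgIpc``); non-finite values are
  imputed to the column median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .data import ScreenDataset
from .exceptions import FeaturizationError

#: pinned descriptor list; exactly 208 names on the supported RDKit version
DESCRIPTOR_NAMES: list[str] = [
    name for name, _ in Descriptors.descList if name not in ("Ipc", "AvgIpc")
]

_DESC_FUNCS = {name: fn for name, fn in Descriptors.descList}


@dataclass
class FeatureMatrix:
    """n x d numeric matrix tagged with its representation.

    Row ``i`` corresponds to dataset record ``i``.  Fingerprint entries
    are 0/1; descriptor entries are finite reals after imputation.
    """

    values: np.ndarray
    representation: str
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _mol_or_raise(smi: str, ident: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise FeaturizationError(f"record {ident!r}: cannot parse SMILES {smi!r}")
    return mol


def fingerprint_matrix(
    ds: ScreenDataset, radius: int = 2, n_bits: int = 1024
) -> FeatureMatrix:
    """Binary folded Morgan fingerprint matrix (n x n_bits).

    Identical canonical structures yield identical rows; featurization is
    deterministic.  A record that cannot be parsed raises
    :class:`FeaturizationError` naming the record — datasets are expected
    to be standardized first.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(ds), n_bits), dtype=np.float64)
    ids = ds.frame["compound_id"]
    for i, smi in enumerate(ds.frame["smiles"]):
        mol = _mol_or_raise(smi, ids.iloc[i])
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = 1.0
    return FeatureMatrix(out, "fingerprint", {"radius": radius, "n_bits": n_bits})


def descriptor_matrix(ds: ScreenDataset) -> FeatureMatrix:
    """Real-valued descriptor matrix (n x 208).

    Column order follows :data:`DESCRIPTOR_NAMES`.  NaN/inf values are
    imputed to the finite column median (recorded in ``meta``); a column
    more than half non-finite triggers a warning.
    """
    missing = [n for n in DESCRIPTOR_NAMES if n not in _DESC_FUNCS]
    if missing:
        raise FeaturizationError(f"descriptor backend lacks: {missing}")

    n, d = len(ds), len(DESCRIPTOR_NAMES)
    out = np.empty((n, d), dtype=np.float64)
    ids = ds.frame["compound_id"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, smi in enumerate(ds.frame["smiles"]):
            mol = _mol_or_raise(smi, ids.iloc[i])
            for j, name in enumerate(DESCRIPTOR_NAMES):
                try:
                    out[i, j] = _DESC_FUNCS[name](mol)
                except Exception:
                    out[i, j] = np.nan

    imputed_cols: dict[str, int] = {}
    bad = ~np.isfinite(out)
    for j in np.flatnonzero(bad.any(axis=0)):
        col_bad = bad[:, j]
        if col_bad.mean() > 0.5:
            warnings.warn(
                f"descriptor {DESCRIPTOR_NAMES[j]!r}: "
                f"{col_bad.mean():.0%} non-finite values"
            )
        finite = out[~col_bad, j]
        fill = float(np.median(finite)) if finite.size else 0.0
        out[col_bad, j] = fill
        imputed_cols[DESCRIPTOR_NAMES[j]] = int(col_bad.sum())

    return FeatureMatrix(
        out, "descriptor", {"names": DESCRIPTOR_NAMES, "imputed": imputed_cols}
    )
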