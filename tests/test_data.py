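"""Screen-table loading, standardization and splitting."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from htsval.data import (
    ScreenDataset,
    SplitSpec,
    build_splits,
    load_screen_csv,
    standardize_records,
    stratified_indices,
)
from htsval.exceptions import (
    ConfigError,
    EmptyDatasetError,
    SchemaError,
    StratificationError,
)


def test_load_passthrough_and_missing_confirmatory(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("smiles,score,primary\nCCO,50,1\nCCN,20,0\n")
    ds = load_screen_csv(p)
    assert len(ds) == 2
    assert ds.meta["load_report"]["n_dropped"] == 0
    assert np.all(np.isnan(ds.confirmatory_labels))


def test_load_drops_malformed_smiles_with_report(tmp_path):
    p = tmp_path / "t.csv"
    rows = ["CCO,10,0", "CCN,20,0", "xx(((bad,30,1", "c1ccccc1,40,1", "CC,50,0"]
    p.write_text("smiles,score,primary\n" + "\n".join(rows) + "\n")
    ds = load_screen_csv(p)
    assert len(ds) == 4
    assert ds.meta["load_report"]["n_dropped"] == 1
    assert ds.meta["load_report"]["reasons"]["unparsable_smiles"] == 1


def test_load_missing_column_and_empty(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("smiles,primary\nCCO,1\n")
    with pytest.raises(SchemaError):
        load_screen_csv(p)
    p2 = tmp_path / "t2.csv"
    p2.write_text("smiles,score,primary\nbadsmiles(((,10,1\n")
    with pytest.raises(EmptyDatasetError):
        load_screen_csv(p2)


def test_load_rescales_out_of_range_scores(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("smiles,score,primary\nCCO,-3,0\nCCN,0,0\nCC,7,1\n")
    ds = load_screen_csv(p)
    s = ds.activity_scores
    assert s.min() == 0.0 and s.max() == 100.0
    assert "score_rescaled_from" in ds.meta["load_report"]


def _ds(rows):
    frame = pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "smiles",
            "activity_score",
            "primary_label",
            "confirmatory_label",
        ],
    )
    return ScreenDataset(frame)


def test_standardize_canonicalizes_and_dedups():
    # three spellings of benzene + two distinct molecules -> 3 records
    ds = _ds(
        [
            ["a", "C1=CC=CC=C1", 10.0, 0, np.nan],
            ["b", "c1ccccc1", 20.0, 1, np.nan],
            ["c", "c1ccccc1C", 30.0, 0, np.nan],
            ["d", "C1=CC=CC=C1", 15.0, 0, np.nan],
            ["e", "CCO", 5.0, 0, np.nan],
        ]
    )
    out = standardize_records(ds)
    assert len(out) == 3
    benzene = Chem.MolToSmiles(Chem.MolFromSmiles("C1=CC=CC=C1"))
    row = out.frame[out.frame.smiles == benzene].iloc[0]
    assert row["compound_id"] == "a"  # first occurrence kept
    assert row["primary_label"] == 1  # active wins on merge
    assert row["activity_score"] == 20.0  # max score


def test_standardize_idempotent_and_permutation_equivariant():
    ds = _ds(
        [
            ["a", "OCC", 1.0, 0, np.nan],
            ["b", "c1ccncc1", 2.0, 1, np.nan],
            ["c", "CC(=O)O", 3.0, 0, np.nan],
        ]
    )
    once = standardize_records(ds)
    twice = standardize_records(once)
    pd.testing.assert_frame_equal(once.frame, twice.frame)

    perm = _ds(
        [
            ["c", "CC(=O)O", 3.0, 0, np.nan],
            ["a", "OCC", 1.0, 0, np.nan],
            ["b", "c1ccncc1", 2.0, 1, np.nan],
        ]
    )
    out_p = standardize_records(perm)
    assert sorted(out_p.frame.smiles) == sorted(once.frame.smiles)


def test_round_trip_write_load(tmp_path, small_screen):
    ds, _, _ = small_screen
    path = tmp_path / "rt.csv"
    ds.to_csv(path)
    back = load_screen_csv(path)
    assert len(back) == len(ds)
    assert back.frame["compound_id"].tolist() == ds.frame["compound_id"].tolist()
    np.testing.assert_allclose(back.activity_scores, ds.activity_scores)
    np.testing.assert_array_equal(back.primary_labels, ds.primary_labels)
    np.testing.assert_array_equal(
        np.isnan(back.confirmatory_labels), np.isnan(ds.confirmatory_labels)
    )


def test_build_splits_top_decile_by_score():
    n = 100
    rows = [[f"c{i}", "CCO", float(i + 1), int(i % 10 == 0), np.nan] for i in range(n)]
    ds = _ds(rows)
    spec = build_splits(ds, seed=0)
    # scores 1..100 distinct: val = the 10 records with scores 91..100
    assert sorted(ds.activity_scores[spec.val_idx]) == [float(s) for s in range(91, 101)]
    # exact partition
    assert len(np.intersect1d(spec.train_idx, spec.val_idx)) == 0
    assert len(spec.train_idx) + len(spec.val_idx) == n


def test_build_splits_tie_break_deterministic():
    rows = [[f"c{i}", "CCO", 50.0, int(i < 5), np.nan] for i in range(40)]
    ds = _ds(rows)
    a = build_splits(ds, seed=3)
    b = build_splits(ds, seed=3)
    np.testing.assert_array_equal(a.val_idx, b.val_idx)
    np.testing.assert_array_equal(a.init_idx, b.init_idx)
    # all-tied scores: ties broken by ascending index
    np.testing.assert_array_equal(a.val_idx, np.arange(4))


def test_stratified_init_exact_arithmetic():
    # 2000 records, 200 actives, 1.5% init -> 30 picks with exactly 3 actives
    labels = np.zeros(2000, dtype=np.int64)
    labels[:200] = 1
    picked = stratified_indices(labels, np.arange(2000), 30, seed=1)
    assert len(picked) == 30
    assert labels[picked].sum() == 3


def test_split_errors():
    rows = [[f"c{i}", "CCO", float(i), 1 if i == 0 else 0, np.nan] for i in range(30)]
    ds = _ds(rows)
    with pytest.raises(ConfigError):
        build_splits(ds, SplitSpec(val_fraction=1.5))
    no_actives = _ds([[f"c{i}", "CCO", float(i), 0, np.nan] for i in range(30)])
    with pytest.raises(StratificationError):
        build_splits(no_actives)
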