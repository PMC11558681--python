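"""False/true-positive triage: ranking, benchmarks, evaluation."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from htsval.data import ScreenDataset
from htsval.exceptions import ConfigError, DegenerateInputError
from htsval.triage import (
    TriageConfig,
    alert_count,
    alert_counts,
    evaluate_triage,
    fp_nominee_diversity,
    rank_candidates,
)
from htsval.valuation.base import ImportanceResults, ValuationConfig


def _screen(n_act=40, n_inact=60, conf_pattern=None):
    n = n_act + n_inact
    primary = np.array([1] * n_act + [0] * n_inact)
    conf = np.full(n, np.nan)
    if conf_pattern is None:
        conf_pattern = [1, 0] * (n_act // 2)
    conf[:len(conf_pattern)] = conf_pattern
    frame = pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(n)],
            "smiles": ["CCO"] * n,
            "activity_score": np.linspace(90, 10, n),
            "primary_label": primary,
            "confirmatory_label": conf,
        }
    )
    return ScreenDataset(frame)


def _imp(scores, engine="mvsa", mode="self"):
    return ImportanceResults(np.asarray(scores, float), ValuationConfig(engine, mode))


def test_self_mode_orientation_sort_contract():
    ds = _screen(3, 2, conf_pattern=[1, 0, 1])
    imp = _imp([3.0, 1.0, 2.0, 0.0, 0.0])
    res = rank_candidates(ds, importance=imp)
    np.testing.assert_array_equal(res.fp_order, [0, 2, 1])


def test_test_mode_orientation_reversed():
    ds = _screen(3, 2, conf_pattern=[1, 0, 1])
    imp = _imp([3.0, 1.0, 2.0, 0.0, 0.0], engine="knn_shapley", mode="test")
    res = rank_candidates(ds, importance=imp)
    np.testing.assert_array_equal(res.fp_order, [1, 2, 0])


def test_nominee_sizes_and_disjointness():
    ds = _screen(40, 10)
    imp = _imp(np.linspace(1, 0, 50))
    res = rank_candidates(ds, importance=imp, cfg=TriageConfig(decile_fraction=0.10))
    assert len(res.fp_nominees) == 4 and len(res.tp_nominees) == 4
    assert len(np.intersect1d(res.fp_nominees, res.tp_nominees)) == 0


def test_alert_counts_match_direct_substructure_check():
    # acyl chloride trips the GSK catalog; ethanol fails REOS size rules only
    smiles = ["O=C(Cl)c1ccccc1", "CCO"]
    counts = alert_counts(smiles)
    from htsval.triage import _gsk_catalog, _REOS_RULES

    for smi, c in zip(smiles, counts):
        mol = Chem.MolFromSmiles(smi)
        expected = len(_gsk_catalog().GetMatches(mol)) + sum(
            not (lo <= fn(mol) <= hi) for _, fn, lo, hi in _REOS_RULES
        )
        assert c == expected
    assert counts[0] > 0


def test_filter_benchmark_ranks_alerted_compounds_first():
    ds = _screen(4, 2, conf_pattern=[1, 0, 1, 0])
    ds.frame.loc[0, "smiles"] = "CC(C)Cc1ccc(cc1)C(C)C(=O)O"  # clean drug-like
    ds.frame.loc[1, "smiles"] = "O=C(Cl)c1ccccc1"  # alert-bearing
    res = rank_candidates(ds, benchmark="filters")
    assert alert_count("O=C(Cl)c1ccccc1") > alert_count("CC(C)Cc1ccc(cc1)C(C)C(=O)O")
    assert res.fp_order[0] == 1


def test_evaluate_triage_hand_example():
    # 10 labeled actives, 4 FPs; nominee decile of size 1 holding an FP
    conf = [0, 1, 1, 0, 1, 1, 0, 1, 0, 1]
    ds = _screen(10, 10, conf_pattern=conf)
    scores = np.concatenate([np.linspace(10, 1, 10), np.zeros(10)])
    res = rank_candidates(ds, importance=_imp(scores), cfg=TriageConfig(0.10))
    reports = evaluate_triage(res, ds, TriageConfig(0.10))
    fp = reports["fp"]
    assert fp.base_rate == pytest.approx(0.4)
    assert fp.values["precision"] == 1.0  # rank-0 active is an FP
    assert fp.values["relative_precision"] == pytest.approx(0.6)


def test_perfect_fp_ranking_relative_precision():
    conf = [0] * 4 + [1] * 6
    ds = _screen(10, 10, conf_pattern=conf)
    scores = np.concatenate([np.linspace(10, 1, 10), np.zeros(10)])
    res = rank_candidates(ds, importance=_imp(scores), cfg=TriageConfig(0.3))
    reports = evaluate_triage(res, ds, TriageConfig(0.3))
    assert reports["fp"].values["precision"] == 1.0
    assert reports["fp"].values["relative_precision"] == pytest.approx(1 - 0.4)


def test_reversed_ranking_bedroc_near_zero():
    n_act = 100
    conf = [0] * 10 + [1] * 90
    ds = _screen(n_act, 10, conf_pattern=conf)
    # worst ranking for the FP task: FPs ranked last
    scores = np.concatenate([np.linspace(1, 100, n_act), np.zeros(10)])
    res = rank_candidates(ds, importance=_imp(scores))
    reports = evaluate_triage(res, ds)
    assert reports["fp"].values["bedroc"] <= 0.01


def test_missing_orientation_and_no_confirmatory_errors():
    ds = _screen(4, 2, conf_pattern=[1, 0, 1, 0])
    with pytest.raises(ConfigError):
        rank_candidates(ds, importance=_imp([1, 2, 3, 4, 0, 0], engine="bogus"))
    ds2 = _screen(4, 2, conf_pattern=[np.nan] * 4)
    res = rank_candidates(ds2, importance=_imp([1, 2, 3, 4, 0, 0]))
    with pytest.raises(DegenerateInputError):
        evaluate_triage(res, ds2)


def test_fp_nominee_diversity_readout():
    ds = _screen(20, 10)
    rng = np.random.default_rng(0)
    feats = (rng.random((30, 64)) < 0.2).astype(float)
    res = rank_candidates(ds, importance=_imp(rng.random(30)))
    div = fp_nominee_diversity(res, feats)
    assert 0.0 <= div <= 1.0
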