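"""Active-learning campaign mechanics."""

import numpy as np
import pytest

from htsval.active_learning import ALConfig, run_campaign, select_batch
from htsval.exceptions import ConfigError
from htsval.synth import SynthConfig, generate_screen

_ENGINE = {"engine": {"lgbm_params": {"min_child_samples": 5}}}


@pytest.fixture(scope="module")
def library():
    return generate_screen(
        SynthConfig(n=1000, active_rate=0.05, fp_rate=0.0, d=64, seed=21)
    )


def test_random_strategy_partition_and_determinism(library):
    ds, feats, _ = library
    cfg = ALConfig(n_steps=4, step_fraction=0.02, strategy="random", seed=5)
    t1 = run_campaign(ds, feats, cfg)
    t2 = run_campaign(ds, feats, cfg)
    all_idx = np.concatenate(t1.step_idx)
    assert len(all_idx) == len(np.unique(all_idx))  # pairwise disjoint
    assert all(len(s) == round(0.02 * len(ds)) for s in t1.step_idx)
    for a, b in zip(t1.step_idx, t2.step_idx):
        np.testing.assert_array_equal(a, b)
    assert t1.cum_actives == sorted(t1.cum_actives)  # non-decreasing


def test_exhausting_library_finds_every_active(library):
    ds, feats, _ = library
    cfg = ALConfig(n_steps=10, step_fraction=0.1, strategy="random", seed=0)
    trace = run_campaign(ds, feats, cfg)
    assert trace.cum_fraction[-1] == pytest.approx(1.0)


def test_truncated_final_batch_flagged(library):
    ds, feats, _ = library
    cfg = ALConfig(n_steps=3, step_fraction=0.3, strategy="random", seed=1)
    trace = run_campaign(ds, feats, cfg)
    assert any("truncated" in f for f in trace.flags)


def test_greedy_and_importance_beat_random(library):
    ds, feats, _ = library
    found = {}
    for strategy in ("random", "greedy", "importance"):
        cfg = ALConfig(
            n_steps=3, step_fraction=0.03, strategy=strategy, seed=2,
            engine_params=_ENGINE,
        )
        found[strategy] = run_campaign(ds, feats, cfg).cum_actives[-1]
    assert found["greedy"] > found["random"]
    assert found["importance"] > found["random"]


def test_select_batch_truncation_and_determinism(library):
    ds, feats, _ = library
    y = ds.primary_labels
    labeled = np.arange(100)
    remainder = np.arange(100, 108)
    cfg = ALConfig(n_steps=1, strategy="greedy", seed=3)
    idx, flags = select_batch(labeled, remainder, feats.values, y[labeled], 20, cfg, 1)
    np.testing.assert_array_equal(idx, remainder)  # whole remainder returned
    assert flags

    remainder = np.arange(100, 400)
    a, _ = select_batch(labeled, remainder, feats.values, y[labeled], 15, cfg, 1)
    b, _ = select_batch(labeled, remainder, feats.values, y[labeled], 15, cfg, 1)
    np.testing.assert_array_equal(a, b)


def test_single_class_labeled_falls_back_to_random(library):
    ds, feats, _ = library
    y = ds.primary_labels
    inactives = np.flatnonzero(y == 0)[:50]
    remainder = np.setdiff1d(np.arange(len(ds)), inactives)
    cfg = ALConfig(n_steps=1, strategy="greedy", seed=4)
    _, flags = select_batch(
        inactives, remainder, feats.values, y[inactives], 10, cfg, 1
    )
    assert any("single-class" in f for f in flags)


def test_config_validation():
    with pytest.raises(ConfigError):
        ALConfig(n_steps=1, step_fraction=0.7)
    with pytest.raises(ConfigError):
        ALConfig(n_steps=200, step_fraction=0.4)
    with pytest.raises(ConfigError):
        ALConfig(n_steps=1, strategy="bogus")
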