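"""Ranking metrics and the paired-comparison harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import friedmanchisquare

from htsval.exceptions import ConfigError, DegenerateInputError
from htsval.metrics import (
    average_precision,
    bedroc,
    bedroc_from_order,
    benjamini_hochberg,
    enrichment_factor,
    method_comparison,
    precision_at,
    rank_order,
)


def _direct_bedroc(ranks, n, N, a):
    """Independent direct-sum evaluation of the early-recognition formula."""
    ranks = np.asarray(ranks, dtype=float)
    Ra = n / N
    s = np.exp(-a * ranks / N).sum()
    rie = (s / n) / ((1 / N) * (1 - np.exp(-a)) / (np.exp(a / N) - 1))
    return rie * Ra * np.sinh(a / 2) / (
        np.cosh(a / 2) - np.cosh(a / 2 - a * Ra)
    ) + 1 / (1 - np.exp(a * (1 - Ra)))


class TestBedroc:
    def test_perfect_and_reversed(self):
        top = bedroc(np.arange(1, 11), 10, 1000, 20)
        bottom = bedroc(np.arange(991, 1001), 10, 1000, 20)
        assert top >= 0.99
        assert bottom <= 0.01
        assert top == pytest.approx(_direct_bedroc(np.arange(1, 11), 10, 1000, 20), abs=1e-12)

    def test_matches_direct_sum_on_random_rankings(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(20, 500))
            n = int(rng.integers(1, N // 2))
            ranks = rng.choice(np.arange(1, N + 1), size=n, replace=False)
            v = bedroc(ranks, n, N, 20)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(_direct_bedroc(ranks, n, N, 20), abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            bedroc([1], 0, 10)
        with pytest.raises(ConfigError):
            bedroc([1, 1], 2, 10)


class TestEnrichmentFactor:
    def test_closed_forms(self):
        order = np.arange(100)
        # exactly 1 of 10 positives in the top 10 -> EF = 1
        positives = np.array([5, 20, 30, 40, 50, 60, 70, 80, 90, 95])
        assert enrichment_factor(order, positives, 0.10) == pytest.approx(1.0)
        # all 10 in the top 10 -> EF = 10
        assert enrichment_factor(order, np.arange(10), 0.10) == pytest.approx(10.0)

    def test_hand_evaluation(self):
        # N=50, n_pos=5, top-5 holds 2 -> (2/5)/(5/50) = 4
        order = np.arange(50)
        positives = np.array([0, 3, 10, 20, 30])
        assert enrichment_factor(order, positives, 0.10) == pytest.approx(4.0)

    def test_bound(self):
        order = np.arange(40)
        assert enrichment_factor(order, np.arange(4), 0.10) <= 1 / 0.10


class TestPrecision:
    def test_perfect_and_hand(self):
        order = np.arange(10)
        prec, rel = precision_at(order, np.arange(4), k=4)
        assert prec == 1.0 and rel == pytest.approx(1 - 0.4)
        prec, _ = precision_at(np.array([0, 1, 2]), np.array([0, 2]), k=2)
        assert prec == pytest.approx(0.5)

    def test_cutoff_error(self):
        with pytest.raises(ConfigError):
            precision_at(np.arange(5), [0], k=6)


class TestAveragePrecision:
    def test_closed_forms(self):
        assert average_precision(np.arange(5), np.arange(2)) == 1.0
        # positives at ranks 1 and 3 of 3 -> (1 + 2/3)/2
        assert average_precision(np.array([0, 1, 2]), np.array([0, 2])) == pytest.approx(
            (1 + 2 / 3) / 2
        )

    def test_trailing_negatives_invariance(self):
        a = average_precision(np.array([0, 1, 2]), np.array([0, 2]))
        b = average_precision(np.arange(6), np.array([0, 2]))
        assert a == b


@settings(max_examples=50, deadline=None)
@given(
    scores=st.lists(
        st.floats(-100, 100, allow_nan=False), min_size=8, max_size=40, unique=True
    ),
    n_pos=st.integers(1, 4),
)
def test_rank_metrics_invariant_under_monotone_transform(scores, n_pos):
    """Rank metrics depend only on the ordering of tie-free scores."""
    scores = np.array(scores)
    positives = np.argsort(scores)[-n_pos:]  # make high scores positive-ish
    o1 = rank_order(scores)
    # strictly monotone, collision-free transform: replace scores by ranks
    ranks = scores.argsort().argsort().astype(np.float64)
    o2 = rank_order(ranks * 7.0 + 3.0)
    np.testing.assert_array_equal(o1, o2)
    assert bedroc_from_order(o1, positives) == bedroc_from_order(o2, positives)
    assert enrichment_factor(o1, positives, 0.25) == enrichment_factor(o2, positives, 0.25)


class TestMethodComparison:
    def test_bh_hand_computation(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_degenerate_identical_vectors(self):
        v = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        rep = method_comparison({"a": v, "b": v.copy()}, reference="b")
        assert rep.degenerate
        assert rep.tests[0]["p_adjusted"] == 1.0

    def test_friedman_matches_textbook_formula(self):
        # tie-free method x dataset table; chi2_F = 12n/(k(k+1)) sum(Rbar - (k+1)/2)^2
        vals = {
            "a": np.array([1.0, 1.2, 0.9, 1.1]),
            "b": np.array([2.0, 2.5, 1.8, 2.2]),
            "c": np.array([0.5, 0.4, 0.6, 0.3]),
        }
        table = np.vstack(list(vals.values())).T  # datasets x methods
        ranks = np.argsort(np.argsort(table, axis=1), axis=1) + 1
        k, n = 3, 4
        chi2 = 12 * n / (k * (k + 1)) * np.sum((ranks.mean(0) - (k + 1) / 2) ** 2)
        rep = method_comparison(vals, reference="a")
        assert rep.values["friedman_statistic"] == pytest.approx(chi2)
        stat, _ = friedmanchisquare(*vals.values())
        assert chi2 == pytest.approx(stat)

    def test_mismatched_lengths(self):
        with pytest.raises(ConfigError):
            method_comparison(
                {"a": np.arange(5), "b": np.arange(4)}, reference="a"
            )
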