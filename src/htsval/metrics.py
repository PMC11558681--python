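"""Ranking metrics and the paired statistical-comparison harness.

Early-recognition metrics operate on the *ranks* of the positives within
a ranking of N items (rank 1 = best), so they are invariant to any
tie-free monotone transform of the underlying scores:

* BEDROC with exponential weight parameter alpha (default 20),
  normalised to [0, 1] following the standard early-recognition
  parameterisation (Truchon & Bayly):

      RIE    = mean_i exp(-alpha * r_i / N) /
               [ (1/N) * (1 - e^-alpha) / (e^(alpha/N) - 1) ]
      BEDROC = RIE * Ra * sinh(a/2) / (cosh(a/2) - cosh(a/2 - a*Ra))
               + 1 / (1 - e^(alpha * (1 - Ra)))         with Ra = n/N

* enrichment factor at a top fraction (default 10%), with a ceiling
  cutoff: EF = (hits in top ceil(f*N) / ceil(f*N)) / (n_pos / N)
* precision over a top-k or top-fraction cutoff and its excess over the
  base rate ("relative precision")
* average precision (mean of precision at each positive's rank)

Method comparison follows the screening-benchmark convention: a Friedman
omnibus test across methods, then pairwise two-sided Wilcoxon signed-rank
tests against a reference method with Benjamini-Hochberg step-up FDR
adjustment at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, DegenerateInputError


@dataclass
class MetricConfig:
    alpha_bedroc: float = 20.0
    ef_fraction: float = 0.10
    k_precision: float | int = 0.10

    def __post_init__(self) -> None:
        if self.alpha_bedroc <= 0:
            raise ConfigError("alpha_bedroc must be > 0")
        if not (0 < self.ef_fraction < 1):
            raise ConfigError("ef_fraction must lie in (0, 1)")


@dataclass
class MetricReport:
    """Metric values plus (optionally) paired-test statistics."""

    values: dict = field(default_factory=dict)
    base_rate: float | None = None
    per_replicate: dict = field(default_factory=dict)
    tests: list = field(default_factory=list)
    degenerate: bool = False


def _ranks_from_order(order: np.ndarray, positives: np.ndarray) -> np.ndarray:
    """1-based ranks of the positive items within an ordering of indices."""
    pos = np.zeros(len(order), dtype=bool)
    pos[np.asarray(positives)] = True
    return np.flatnonzero(pos[order]) + 1


def rank_order(scores: np.ndarray, descending: bool = True) -> np.ndarray:
    """Indices sorted by score; ties resolved by ascending index (stable)."""
    scores = np.asarray(scores, dtype=np.float64)
    key = -scores if descending else scores
    return np.argsort(key, kind="stable")


def bedroc(positive_ranks, n_pos: int, n_total: int, alpha: float = 20.0) -> float:
    """BEDROC in [0, 1] from the 1-based ranks of the positives."""
    r = np.asarray(positive_ranks, dtype=np.float64)
    if n_pos <= 0 or n_pos >= n_total:
        raise DegenerateInputError("bedroc needs 0 < n_pos < N")
    if (
        len(r) != n_pos
        or len(np.unique(r)) != n_pos
        or (r < 1).any()
        or (r > n_total).any()
    ):
        raise ConfigError("positive_ranks must be n_pos distinct ranks in 1..N")
    a, N, Ra = float(alpha), float(n_total), n_pos / n_total
    rie = np.exp(-a * r / N).mean() / ((1.0 / N) * (1 - np.exp(-a)) / (np.exp(a / N) - 1))
    return float(
        rie * Ra * np.sinh(a / 2) / (np.cosh(a / 2) - np.cosh(a / 2 - a * Ra))
        + 1.0 / (1 - np.exp(a * (1 - Ra)))
    )


def bedroc_from_order(order: np.ndarray, positives, alpha: float = 20.0) -> float:
    ranks = _ranks_from_order(order, positives)
    return bedroc(ranks, len(ranks), len(order), alpha)


def enrichment_factor(order: np.ndarray, positives, fraction: float = 0.10) -> float:
    """EF at the top fraction: hit rate in the top over the overall rate."""
    order = np.asarray(order)
    N = len(order)
    cutoff = int(np.ceil(fraction * N))
    if cutoff < 1:
        raise ConfigError("fraction * N must be >= 1")
    n_pos = len(np.asarray(positives))
    if n_pos == 0:
        raise DegenerateInputError("no positives")
    hits = len(np.intersect1d(order[:cutoff], positives))
    return (hits / cutoff) / (n_pos / N)


def precision_at(order: np.ndarray, positives, k: float | int = 0.10) -> tuple[float, float]:
    """(precision, precision - base rate) over the top-k cutoff.

    ``k`` may be an absolute count (int >= 1) or a fraction in (0, 1),
    in which case the cutoff is ``round(k * N)`` (at least 1).
    """
    order = np.asarray(order)
    N = len(order)
    cutoff = int(k) if k >= 1 else max(int(round(k * N)), 1)
    if cutoff > N:
        raise ConfigError(f"cutoff {cutoff} exceeds ranking length {N}")
    n_pos = len(np.asarray(positives))
    base = n_pos / N
    hits = len(np.intersect1d(order[:cutoff], positives))
    prec = hits / cutoff
    return prec, prec - base


def average_precision(order: np.ndarray, positives) -> float:
    """Step-interpolated area under precision-recall: the mean, over the
    positives, of the precision at each positive's rank."""
    order = np.asarray(order)
    n_pos = len(np.asarray(positives))
    if n_pos == 0 or n_pos == len(order):
        raise DegenerateInputError("average precision needs both classes")
    ranks = np.sort(_ranks_from_order(order, positives))
    hits = np.arange(1, n_pos + 1)
    return float((hits / ranks).mean())


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def method_comparison(
    values: dict[str, np.ndarray],
    reference: str,
    alpha: float = 0.05,
) -> MetricReport:
    """Compare methods over paired per-dataset (or per-seed) values.

    Runs a Friedman omnibus test across all methods, then two-sided
    Wilcoxon signed-rank tests of each method against ``reference`` with
    BH adjustment across the pairwise family.  All-zero difference pairs
    are flagged degenerate with p = 1.
    """
    names = list(values)
    if reference not in names:
        raise ConfigError(f"reference {reference!r} not among methods {names}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise ConfigError("paired value vectors must have equal length")
    if len(names) < 2:
        raise ConfigError("need at least two methods")

    report = MetricReport(per_replicate={k: v.tolist() for k, v in arrays.items()})
    if len(names) >= 3:
        fstat, fp = stats.friedmanchisquare(*arrays.values())
        report.values["friedman_statistic"] = float(fstat)
        report.values["friedman_p"] = float(fp)

    raws, pairs = [], []
    for name in names:
        if name == reference:
            continue
        diff = arrays[name] - arrays[reference]
        if np.all(diff == 0):
            raws.append(1.0)
            report.degenerate = True
            stat = 0.0
        else:
            res = stats.wilcoxon(
                arrays[name], arrays[reference], zero_method="wilcox", method="auto"
            )
            stat, p = float(res.statistic), float(res.pvalue)
            raws.append(p)
        pairs.append((name, stat))
    adjusted = benjamini_hochberg(raws)
    for (name, stat), p_raw, p_adj in zip(pairs, raws, adjusted):
        report.tests.append(
            {
                "pair": (name, reference),
                "statistic": stat,
                "p_raw": float(p_raw),
                "p_adjusted": float(max(p_adj, p_raw)),
                "significant": bool(p_adj < alpha),
            }
        )
    return report
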