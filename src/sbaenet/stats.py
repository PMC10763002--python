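"""Statistical primitives shared by every pipeline stage.

Thin, contract-checked wrappers around scipy/statsmodels plus a hand-built
one-sample Wilcoxon signed-rank test (exact via dynamic programming for small
samples, which handles midranks from tied data; normal approximation with tie
correction otherwise).

Conventions
-----------
* Fisher's exact test is two-sided by default; the direction of a sex bias is
  read from the sign of the log reporting odds ratio, not from the test tail.
* Zero differences in the signed-rank test are dropped before ranking
  (Wilcoxon's convention); the number dropped is recorded on the result.
* Rank tests use midranks with the usual tie correction of the normal-
  approximation variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PValueVector",
    "fisher_exact_2x2",
    "bh_adjust",
    "hypergeom_overlap_test",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank_one_sample",
    "pearson_cor_test",
]

# exact signed-rank p-values up to this sample size (configurable per call)
EXACT_SIGNED_RANK_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    alternative: str = "two-sided"
    method: str = ""
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class PValueVector:
    """Labelled vector of probabilities, e.g. raw or BH-adjusted p-values."""

    values: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must be aligned")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")


def _validate_counts(*cells: float) -> None:
    for c in cells:
        if c < 0 or int(c) != c:
            raise ValueError(f"cell counts must be non-negative integers, got {c}")


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test of a 2x2 contingency table.

    The two-sided p-value sums the probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed that of the
    observed table.
    """
    _validate_counts(a, b, c, d)
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return TestResult(statistic=float(odds), p_value=float(p),
                      alternative=alternative, method="fisher-exact")


def bh_adjust(p: PValueVector | Sequence[float]) -> PValueVector:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    if isinstance(p, PValueVector):
        values, labels = p.values, p.labels
    else:
        values = np.asarray(list(p), dtype=float)
        labels = list(range(len(values)))
    if values.size == 0:
        raise ValueError("empty p-value vector")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(values, method="fdr_bh")[1]
    return PValueVector(values=np.minimum(adj, 1.0), labels=list(labels))


def hypergeom_overlap_test(universe: int, size_a: int, size_b: int,
                           overlap: int) -> TestResult:
    """Upper-tail hypergeometric test, P(X >= overlap).

    X counts the overlap of a random size-b subset of the universe with a
    fixed size-a subset.
    """
    _validate_counts(universe, size_a, size_b, overlap)
    if size_a > universe or size_b > universe:
        raise ValueError("set sizes cannot exceed the universe")
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed the smaller set")
    p = float(sps.hypergeom.sf(overlap - 1, universe, size_a, size_b))
    return TestResult(statistic=float(overlap), p_value=min(p, 1.0),
                      alternative="greater", method="hypergeometric")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      continuity: bool = True,
                      alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when both samples are small and tie-free, otherwise the normal
    approximation with continuity and tie correction. The statistic reported
    is the Mann-Whitney U of `x` (equal to R's ``wilcox.test`` W).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           use_continuity=continuity, method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative=alternative, method="wilcoxon-rank-sum")


def _signed_rank_exact_cdf(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of the doubled positive-rank sum, by subset-sum DP.

    Midranks are multiples of 0.5, so doubling makes every rank an integer
    and the distribution of 2*W+ lives on {0, ..., sum(2r)}.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank_one_sample(x: Sequence[float], mu: float = 0.0,
                                    alternative: str = "two-sided",
                                    exact_max_n: int = EXACT_SIGNED_RANK_MAX_N
                                    ) -> TestResult:
    """One-sample Wilcoxon signed-rank test of H0: median(x) == mu.

    Zero differences are dropped before ranking; ties get midranks. Exact
    p-values (valid under ties) for n <= `exact_max_n`, normal approximation
    with tie correction and 0.5 continuity correction otherwise. If every
    value equals `mu` the test is degenerate and returns p = 1 with the
    `degenerate` flag set.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(list(x), dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    d = x - mu
    n_dropped = int((d == 0).sum())
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, alternative=alternative,
                          method="wilcoxon-signed-rank", degenerate=True,
                          extra={"n_dropped": n_dropped, "n_used": 0})
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        doubled = np.rint(2 * ranks).astype(int)
        cdf_counts = _signed_rank_exact_cdf(doubled)
        w2 = int(round(2 * w_plus))
        p_le = float(cdf_counts[: w2 + 1].sum())
        p_ge = float(cdf_counts[w2:].sum())
        method = "wilcoxon-signed-rank-exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
        sd = np.sqrt(var) if var > 0 else np.nan
        if not np.isfinite(sd) or sd == 0:
            return TestResult(statistic=w_plus, p_value=1.0,
                              alternative=alternative,
                              method="wilcoxon-signed-rank", degenerate=True,
                              extra={"n_dropped": n_dropped, "n_used": n})
        p_ge = float(sps.norm.sf((w_plus - mean - 0.5) / sd))
        p_le = float(sps.norm.cdf((w_plus - mean + 0.5) / sd))
        method = "wilcoxon-signed-rank-normal"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(statistic=w_plus, p_value=min(max(p, 0.0), 1.0),
                      alternative=alternative, method=method,
                      extra={"n_dropped": n_dropped, "n_used": n})


def pearson_cor_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided t-test p-value (n-2 df).

    Zero-variance input yields a flagged 'undefined' result rather than an
    exception, so downstream edge typing can classify it explicitly.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(statistic=np.nan, p_value=np.nan,
                          alternative="two-sided", method="pearson",
                          degenerate=True, extra={"undefined": True})
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p),
                      alternative="two-sided", method="pearson")
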