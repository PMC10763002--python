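"""Statistical primitives against independent enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pytest

from sbaenet.stats import (
    PValueVector,
    bh_adjust,
    fisher_exact_2x2,
    hypergeom_overlap_test,
    pearson_cor_test,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank_one_sample,
)


# ---------------------------------------------------------------------------
# oracles (independent of scipy/statsmodels)
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive enumeration over all tables with the observed margins."""
    n, r, col = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    denom = comb(n, r)
    pmf = {k: comb(col, k) * comb(n - col, r - k) / denom
           for k in range(lo, hi + 1)}
    return sum(q for q in pmf.values() if q <= pmf[a] * (1 + 1e-10))


def signed_rank_oracle(x, mu, alternative):
    """Exact p by enumerating all 2^n sign assignments of |x - mu| ranks."""
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.asarray(ws)
    eps = 1e-9
    p_ge = float((ws >= w_obs - eps).mean())
    p_le = float((ws <= w_obs + eps).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_oracle(p):
    """Hand step-up: sort, multiply by m/rank, enforce monotone from the top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_example_5005():
    res = fisher_exact_2x2(5, 0, 0, 5)
    assert res.p_value == pytest.approx(2 / comb(10, 5), abs=1e-12)
    assert res.p_value == pytest.approx(0.00794, abs=5e-6)


def test_fisher_balanced_table_p_one():
    assert fisher_exact_2x2(10, 10, 10, 10).p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(300):
        n = int(rng.integers(1, 41))
        cells = rng.multinomial(n, [0.25] * 4)
        a, b, c, d = (int(v) for v in cells)
        expected = fisher_two_sided_oracle(a, b, c, d)
        got = fisher_exact_2x2(a, b, c, d).p_value
        assert got == pytest.approx(expected, abs=1e-10), (a, b, c, d)


def test_fisher_one_sided_tails_sum():
    # P(X >= a) + P(X <= a) = 1 + P(X == a) for the conditional distribution
    a, b, c, d = 8, 2, 3, 7
    g = fisher_exact_2x2(a, b, c, d, alternative="greater").p_value
    l = fisher_exact_2x2(a, b, c, d, alternative="less").p_value
    n, r, col = a + b + c + d, a + b, a + c
    pmf_a = comb(col, a) * comb(n - col, r - a) / comb(n, r)
    assert g + l == pytest.approx(1.0 + pmf_a, abs=1e-12)


def test_fisher_rejects_bad_counts():
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        fisher_exact_2x2(1.5, 1, 1, 1)
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_worked_example():
    adj = bh_adjust([0.01, 0.04, 0.03, 0.05]).values
    assert adj == pytest.approx([0.04, 0.05, 0.05, 0.05])


def test_bh_matches_hand_step_up(rng):
    for _ in range(50):
        p = rng.random(int(rng.integers(1, 40)))
        assert bh_adjust(p).values == pytest.approx(bh_oracle(p), abs=1e-12)


def test_bh_elementwise_at_least_input(rng):
    p = rng.random(25)
    assert (bh_adjust(p).values >= p - 1e-15).all()


def test_bh_permutation_equivariance(rng):
    p = rng.random(15)
    perm = rng.permutation(15)
    assert bh_adjust(p[perm]).values == pytest.approx(bh_adjust(p).values[perm])


def test_bh_preserves_labels():
    vec = PValueVector(values=np.array([0.2, 0.01]), labels=["x", "y"])
    out = bh_adjust(vec)
    assert out.labels == ["x", "y"]


def test_bh_rejects_empty_and_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

def test_hypergeom_example():
    res = hypergeom_overlap_test(10, 4, 5, 3)
    assert res.p_value == pytest.approx(0.2619, abs=5e-5)


def test_hypergeom_matches_direct_sum():
    # P(X >= k) by direct pmf summation
    U, a, b, k = 30, 12, 9, 5
    total = sum(comb(a, x) * comb(U - a, b - x) for x in range(k, min(a, b) + 1))
    expected = total / comb(U, b)
    assert hypergeom_overlap_test(U, a, b, k).p_value == pytest.approx(expected)


def test_hypergeom_upper_plus_strict_lower_is_one(rng):
    for _ in range(50):
        U = int(rng.integers(2, 60))
        a = int(rng.integers(1, U + 1))
        b = int(rng.integers(1, U + 1))
        k = int(rng.integers(0, min(a, b) + 1))
        upper = hypergeom_overlap_test(U, a, b, k).p_value
        from scipy.stats import hypergeom
        lower_strict = hypergeom.cdf(k - 1, U, a, b)
        assert upper + lower_strict == pytest.approx(1.0, abs=1e-12)


def test_hypergeom_rejects_inconsistent_sizes():
    with pytest.raises(ValueError):
        hypergeom_overlap_test(10, 11, 5, 3)
    with pytest.raises(ValueError):
        hypergeom_overlap_test(10, 4, 5, 5)


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

def test_rank_sum_tiny_exact():
    res = wilcoxon_rank_sum([1, 2], [3, 4])
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)


def test_rank_sum_identical_samples_p_near_one():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert wilcoxon_rank_sum(x, list(x)).p_value > 0.9


def test_rank_sum_large_shift_significant(rng):
    x = rng.normal(0, 1, 20)
    assert wilcoxon_rank_sum(x, x + 1000).p_value < 1e-3


def test_rank_sum_statistic_is_mann_whitney_u():
    # U of x over y: number of (x, y) pairs with x > y (+ half-ties)
    res = wilcoxon_rank_sum([5, 6], [1, 2, 3])
    assert res.statistic == 6.0


def test_rank_sum_rejects_empty():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# one-sample signed-rank
# ---------------------------------------------------------------------------

def test_signed_rank_example_all_below():
    res = wilcoxon_signed_rank_one_sample([1, 2, 3], mu=10, alternative="less")
    assert res.p_value == pytest.approx(0.125, abs=1e-12)
    assert res.method == "wilcoxon-signed-rank-exact"


def test_signed_rank_degenerate_all_equal():
    res = wilcoxon_signed_rank_one_sample([5, 5, 5], mu=5)
    assert res.degenerate
    assert res.p_value == 1.0
    assert res.extra["n_dropped"] == 3


def test_signed_rank_matches_sign_enumeration(rng):
    for _ in range(60):
        n = int(rng.integers(1, 11))
        # integer values force ties/midranks into the comparison
        x = rng.integers(-4, 5, size=n).astype(float)
        mu = float(rng.integers(-2, 3))
        if np.all(x == mu):
            continue
        for alternative in ("two-sided", "greater", "less"):
            expected = signed_rank_oracle(x, mu, alternative)
            got = wilcoxon_signed_rank_one_sample(
                x, mu=mu, alternative=alternative).p_value
            assert got == pytest.approx(expected, abs=1e-10), (x, mu, alternative)


def test_signed_rank_normal_approx_near_half_under_null(rng):
    x = np.concatenate([rng.normal(0, 1, 200), -rng.normal(0, 1, 200)])
    res = wilcoxon_signed_rank_one_sample(x, mu=0.0, alternative="less")
    assert res.method == "wilcoxon-signed-rank-normal"
    assert 0.2 < res.p_value < 0.8


def test_signed_rank_zeros_dropped_count():
    res = wilcoxon_signed_rank_one_sample([2, 2, 3, 5], mu=2)
    assert res.extra["n_dropped"] == 2
    assert res.extra["n_used"] == 2


def test_signed_rank_rejects_empty_and_bad_alternative():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank_one_sample([])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank_one_sample([1.0], alternative="sideways")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def test_pearson_hand_arithmetic():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    r_hand = cov / (x.std() * y.std())
    assert pearson_cor_test(x, y).statistic == pytest.approx(r_hand)


def test_pearson_zero_variance_flagged_not_raised():
    res = pearson_cor_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert res.degenerate
    assert np.isnan(res.statistic)


def test_pearson_rejects_short_or_mismatched():
    with pytest.raises(ValueError):
        pearson_cor_test([1, 2], [1, 2])
    with pytest.raises(ValueError):
        pearson_cor_test([1, 2, 3], [1, 2])
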