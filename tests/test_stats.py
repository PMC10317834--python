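"""Unit and property tests for the elementary statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirlink.stats import (bh_adjust, kmeans, one_sample_t, pca, pearson_corr,
                           wilcoxon_rank_sum, wilcoxon_signed_rank_one_sample)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """O(m^2) min-over-tails BH: adj_i = min over p_j >= p_i of p_j * m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]]
        adj[i] = min(1.0, min(candidates))
    return adj


def ranksum_oracle(a, b):
    """Exact two-sided p by enumerating every group assignment."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    observed = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.asarray(sums)
    lower = np.mean(sums <= observed + 1e-9)
    upper = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2 * min(lower, upper))


def signed_rank_oracle(x, mu):
    d = np.asarray(x, float) - mu
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    sums = [np.sum(ranks[list(signs)]) for k in range(len(d) + 1)
            for signs in itertools.combinations(range(len(d)), k)]
    sums = np.asarray(sums)
    lower = np.mean(sums <= observed + 1e-9)
    upper = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2 * min(lower, upper))


# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,y,r", [
    ([1, 2, 3], [3, 2, 1], -1.0),
    ([1, 2, 3], [1, 2, 3], 1.0),
    ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
])
def test_pearson_known_values(x, y, r):
    res = pearson_corr(x, y)
    assert res.estimate == pytest.approx(r)


def test_pearson_matches_scipy():
    rng = np.random.default_rng(0)
    for n in (5, 10, 40):
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = pearson_corr(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.estimate == pytest.approx(ref_r, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-9)


def test_pearson_degenerate_and_invariance():
    res = pearson_corr([1.0, 1.0, 1.0], [1, 2, 3])
    assert res.degenerate and math.isnan(res.estimate)
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=12), rng.normal(size=12)
    base = pearson_corr(x, y).estimate
    assert pearson_corr(3.5 * x + 2, y).estimate == pytest.approx(base)
    assert pearson_corr(-2 * x + 1, y).estimate == pytest.approx(-base)
    assert pearson_corr(y, x).estimate == pytest.approx(base)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ([0.05], [0.05]),
    ([0.01, 0.04, 0.9], [0.03, 0.06, 0.9]),
])
def test_bh_known_values(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=12))
def test_bh_matches_bruteforce_and_is_monotone(p):
    adj = bh_adjust(p)
    assert adj == pytest.approx(bh_oracle(p))
    p = np.asarray(p)
    assert np.all(adj >= p - 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    assert bh_adjust(p) == pytest.approx(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,p", [
    ([1, 2, 3], [4, 5, 6], 0.1),
    ([1, 2], [3, 4], 1 / 3),
    ([1, 2], [1, 2], 1.0),
])
def test_ranksum_known_values(a, b, p):
    assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(p)


def test_ranksum_exact_matches_enumeration():
    rng = np.random.default_rng(3)
    for n1 in range(1, 5):
        for n2 in range(1, 9 - n1):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # untied
            a, b = vals[:n1], vals[n1:]
            res = wilcoxon_rank_sum(a, b, mode="exact")
            assert res.p_value == pytest.approx(ranksum_oracle(a, b))
            assert res.extra["enumeration"] == math.comb(n1 + n2, n1)


def test_ranksum_ties_fall_back_to_approx():
    with pytest.warns(UserWarning, match="ties"):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3], mode="exact")
    assert res.method.endswith("approx")


@pytest.mark.parametrize("x,mu,p", [
    ([1, 1, 1], 1, 1.0),
    ([1.5, 1.6, 1.7, 1.8, 1.9], 1, 0.0625),
    ([0.5, 1.5], 1, 1.0),
])
def test_signed_rank_known_values(x, mu, p):
    res = wilcoxon_signed_rank_one_sample(x, mu)
    assert res.p_value == pytest.approx(p)
    if p == 1.0 and all(v == mu for v in x):
        assert res.degenerate


def test_signed_rank_exact_matches_enumeration():
    rng = np.random.default_rng(4)
    for n in range(2, 9):
        x = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], n) + 0.25
        res = wilcoxon_signed_rank_one_sample(x, 0.0)
        assert res.p_value == pytest.approx(signed_rank_oracle(x, 0.0))


def test_signed_rank_reports_dropped_zeros():
    res = wilcoxon_signed_rank_one_sample([1.0, 1.0, 2.0, 3.0], mu=1.0)
    assert res.extra["n_zero"] == 2


# ---------------------------------------------------------------------------
# one-sample t
# ---------------------------------------------------------------------------

def test_one_sample_t_examples():
    assert one_sample_t([1, 2, 3], 2).p_value == pytest.approx(1.0)
    res = one_sample_t([2, 4], 0, "greater")
    assert res.statistic == pytest.approx(3.0)
    assert res.p_value == pytest.approx(0.1024, abs=2e-4)
    assert one_sample_t([5, 5, 5], 0).degenerate


def test_one_sample_t_matches_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(1, 2, 15)
    for alt in ("two-sided", "greater", "less"):
        res = one_sample_t(x, 0.5, alt)
        ref = sps.ttest_1samp(x, 0.5, alternative={"two-sided": "two-sided",
                                                   "greater": "greater",
                                                   "less": "less"}[alt])
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def test_kmeans_trivial_cases():
    pts = np.array([[0.0, 0], [2, 2], [4, 4]])
    res = kmeans(pts, k=1, seed=0)
    assert np.allclose(res.centers[0], pts.mean(axis=0))
    res = kmeans(pts, k=3, seed=0)
    assert res.inertia == pytest.approx(0.0)
    with pytest.raises(ValueError):
        kmeans(pts, k=4, seed=0)


def test_kmeans_recovers_separated_groups_and_orders_labels():
    rng = np.random.default_rng(6)
    lo = rng.normal(0, 1, (10, 2))
    hi = rng.normal(100, 1, (10, 2))
    res = kmeans(np.vstack([lo, hi]), k=2, restarts=5, seed=1)
    # label 0 is the high-mean cluster by convention
    assert set(res.labels[:10]) == {1} and set(res.labels[10:]) == {0}
    assert all(b <= a + 1e-9 for a, b in zip(res.inertia_history, res.inertia_history[1:]))


def test_kmeans_deterministic_and_close_to_sklearn():
    from sklearn.cluster import KMeans
    rng = np.random.default_rng(7)
    pts = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(6, 1, (20, 3))])
    a = kmeans(pts, k=2, seed=9)
    b = kmeans(pts, k=2, seed=9)
    assert np.array_equal(a.labels, b.labels)
    ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts)
    assert a.inertia == pytest.approx(ref.inertia_, rel=1e-6)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_line_and_rotation_invariance():
    t = np.linspace(0, 1, 8)
    X = np.c_[t, 2 * t]  # samples on a line
    res = pca(X, 1)
    assert res.variance_explained[0] == pytest.approx(1.0)
    rng = np.random.default_rng(8)
    Y = rng.normal(size=(10, 4))
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    assert pca(Y @ q, 3).variance_explained == pytest.approx(
        pca(Y, 3).variance_explained, rel=1e-9)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(6, 4))
    res = pca(X, 3)
    Xc = X - X.mean(axis=0)
    evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
    assert res.singular_values**2 == pytest.approx(evals[:3], rel=1e-9)
    # scores reproduce the centred Gram spectrum
    gram_evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
    assert (res.scores**2).sum(axis=0) == pytest.approx(gram_evals[:3], rel=1e-9)


def test_pca_constant_matrix():
    res = pca(np.ones((5, 3)), 2)
    assert res.variance_explained == pytest.approx([0, 0])
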