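"""Elementary statistics used throughout the package.

Self-contained implementations of Pearson correlation, Benjamini-Hochberg
adjustment, exact/approximate Wilcoxon tests, the one-sample t-test, Lloyd's
k-means and PCA.  The rank tests enumerate the exact permutation distribution
whenever that is feasible (no ties, small n) and otherwise fall back to the
midrank normal approximation with tie-corrected variance and continuity
correction.  Conventions that are ambiguous in common usage are pinned down
here so results are reproducible:

* two-sided exact p-values are ``2 * min(lower tail, upper tail)`` capped at 1;
* zero differences in the one-sample signed-rank test are dropped (their count
  is reported on the result);
* k-means cluster labels are ordered by descending centre mean, so label 0 is
  always the "high" cluster;
* PCA fixes component signs so the largest-magnitude loading is positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "KMeansResult",
    "PCAResult",
    "pearson_corr",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank_one_sample",
    "one_sample_t",
    "kmeans",
    "pca",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``estimate`` carries the effect estimate where one exists (Pearson r,
    mean difference, ...).  ``degenerate`` flags inputs on which the
    statistic is undefined (for example zero variance); degenerate results
    carry ``p_value = nan`` unless a specific convention applies and are
    returned instead of raising so matrix-scale sweeps can proceed.
    """

    statistic: float
    p_value: float
    method: str
    n: tuple
    estimate: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degenerate and not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    inertia_history: list


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    singular_values: np.ndarray


# ---------------------------------------------------------------------------
# correlation and multiple testing
# ---------------------------------------------------------------------------

def pearson_corr(x, y) -> TestResult:
    """Sample Pearson correlation with a two-sided p from the t transform.

    The p-value uses ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees
    of freedom.  Zero-variance input yields a degenerate result (r undefined)
    rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return TestResult(np.nan, np.nan, "pearson", (n,), estimate=np.nan, degenerate=True)
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(t, min(p, 1.0), "pearson", (n,), estimate=r)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _midranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _ranksum_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Distribution of the rank sum of group 1 over all C(n1+n2, n1) splits.

    Dynamic-programming count over untied ranks 1..n1+n2; entry ``c[w]`` is
    the number of assignments whose group-1 rank sum equals ``w``.
    """
    n = n1 + n2
    max_w = n1 * n
    # c[k][w] = number of k-subsets of ranks seen so far with sum w
    c = np.zeros((n1 + 1, max_w + 1), dtype=float)
    c[0, 0] = 1.0
    for rank in range(1, n + 1):
        upper = min(rank, n1)
        for k in range(upper, 0, -1):
            c[k, rank:] += c[k - 1, :-rank] if rank > 0 else c[k - 1, :]
    return c[n1]


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact mode enumerates the permutation distribution of the rank sum
    (feasible and used automatically when both groups have <= 25 values and
    there are no ties); with ties, exact mode falls back to the midrank
    normal approximation with tie-corrected variance and continuity
    correction, emitting a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < pooled.size
    want_exact = mode == "exact" or (mode == "auto" and n1 <= 25 and n2 <= 25)
    if want_exact and has_ties and mode == "exact":
        warnings.warn("ties present: exact enumeration unavailable, using normal approximation")
    if want_exact and not has_ties:
        counts = _ranksum_exact_counts(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(w, p, "wilcoxon-rank-sum-exact", (n1, n2),
                          extra={"enumeration": int(round(total))})
    # normal approximation with midranks, tie correction, continuity correction
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return TestResult(w, 1.0, "wilcoxon-rank-sum-approx", (n1, n2), degenerate=True)
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(w, p, "wilcoxon-rank-sum-approx", (n1, n2))


def _signed_rank_exact_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of W+ over all 2^n sign patterns for integer ranks 1..n."""
    max_w = int(ranks.sum())
    c = np.zeros(max_w + 1)
    c[0] = 1.0
    for r in ranks.astype(int):
        c[r:] += c[:-r].copy() if r > 0 else c
    return c


def wilcoxon_signed_rank_one_sample(x, mu: float = 0.0) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu``.

    Differences equal to zero are dropped (their count is reported in
    ``extra['n_zero']``).  The exact sign-pattern enumeration is used for
    effective n <= 25 when the absolute differences are untied; otherwise
    the normal approximation with tie correction applies.  All differences
    zero yields a degenerate result with p = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("x must be non-empty")
    d = x - mu
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon-signed-rank", (x.size,),
                          degenerate=True, extra={"n_zero": n_zero})
    absd = np.abs(d)
    ranks = _midranks(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < absd.size
    if n <= 25 and not has_ties:
        counts = _signed_rank_exact_counts(ranks)
        total = counts.sum()  # 2^n
        wi = int(round(w_plus))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(w_plus, p, "wilcoxon-signed-rank-exact", (n,),
                          extra={"n_zero": n_zero, "enumeration": int(round(total))})
    mean_w = n * (n + 1) / 4.0
    _, t_counts = np.unique(absd, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(t_counts**3 - t_counts)) / 48.0
    if var_w <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon-signed-rank-approx", (n,),
                          degenerate=True, extra={"n_zero": n_zero})
    z = (abs(w_plus - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(w_plus, p, "wilcoxon-signed-rank-approx", (n,), extra={"n_zero": n_zero})


def one_sample_t(x, mu: float = 0.0, alternative: str = "two-sided") -> TestResult:
    """One-sample Student t-test of ``mean(x) == mu``.

    ``alternative`` is one of ``two-sided``, ``greater`` (mean > mu) or
    ``less``.  Zero sample variance yields a degenerate result; callers
    should then rely on an empirical p-value instead.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0.0:
        return TestResult(np.nan, np.nan, "one-sample-t", (n,), estimate=m - mu, degenerate=True)
    t = (m - mu) / (s / math.sqrt(n))
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    elif alternative == "greater":
        p = sps.t.sf(t, n - 1)
    else:
        p = sps.t.cdf(t, n - 1)
    return TestResult(t, min(p, 1.0), "one-sample-t", (n,), estimate=m - mu)


# ---------------------------------------------------------------------------
# k-means and PCA
# ---------------------------------------------------------------------------

def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    idx = rng.integers(n)
    centers[0] = points[idx]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    k = centers.shape[0]
    history = []
    labels = None
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(points.shape[0]), new_labels].sum())
        history.append(inertia)
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centers[j] = points[mask].mean(axis=0)
            else:
                # re-seed an emptied cluster from the point farthest from its centre
                far = d2[np.arange(points.shape[0]), new_labels].argmax()
                centers[j] = points[far]
                new_labels[far] = j
        if labels is not None and np.array_equal(labels, new_labels):
            break
        labels = new_labels
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(points.shape[0]), labels].sum())
    history.append(inertia)
    return labels, centers, inertia, history


def kmeans(points, k: int, restarts: int = 10, seed: int = 0) -> KMeansResult:
    """Best-of-restarts Lloyd's k-means with k-means++ seeding.

    Deterministic given ``seed``.  Cluster labels are relabelled by
    descending centre mean, so label 0 is the highest-mean cluster.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D matrix (items x dims)")
    n = points.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds number of items {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        centers0 = _kmeans_pp_init(points, k, rng)
        labels, centers, inertia, history = _lloyd(points, centers0.copy())
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, history)
    labels, centers, inertia, history = best
    order = np.argsort(-centers.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return KMeansResult(relabel[labels], centers[order], inertia, history)


def pca(X, n_components: int | None = None) -> PCAResult:
    """PCA by SVD of the column-centred matrix (samples x features).

    ``variance_explained`` is the per-component fraction of total variance
    (sums to <= 1).  Component signs are fixed so each component's
    largest-magnitude loading is positive.  A constant matrix yields zero
    variance explained.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n, p = X.shape
    max_comp = min(n - 1, p) if n > 1 else 0
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components = {n_components} exceeds min(samples - 1, features) = {max_comp}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    k = n_components
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-magnitude loading per component positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * s
    var_exp = (s**2) / total if total > 0 else np.zeros(k)
    return PCAResult(scores, Vt, var_exp, s)
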