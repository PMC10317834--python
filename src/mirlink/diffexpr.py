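"""Count filtering, CPM, TMM normalization and NB differential expression.

The differential-expression stage is a minimal negative-binomial GLM
likelihood-ratio test in the edgeR tradition: per feature, a log-link NB
model with an offset for the log effective library size, a full model with
one mean per group and a null model with a single mean.  Dispersion is a
common value estimated by profile likelihood on a grid, with per-feature
method-of-moments estimates shrunk toward it.  Log2 fold changes are
moderated with a small prior count so zero groups stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .stats import bh_adjust

__all__ = [
    "CountMatrix",
    "NormalizationState",
    "FilterReport",
    "DispersionFit",
    "filter_low_counts",
    "cpm",
    "tmm_factors",
    "nb_fit_dispersion",
    "nb_lrt",
    "select_signature",
]


class CountMatrix:
    """Feature-by-sample matrix of nonnegative integer read counts."""

    def __init__(self, counts, feature_ids, sample_ids, feature_type: str = "mRNA"):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (features x samples)")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        feature_ids = list(map(str, feature_ids))
        sample_ids = list(map(str, sample_ids))
        if counts.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError("counts shape inconsistent with identifier lists")
        for label, ids in (("feature", feature_ids), ("sample", sample_ids)):
            seen = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {label} id: {i!r}")
                seen.add(i)
        self.counts = counts
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.feature_type = feature_type
        self._fpos = {f: i for i, f in enumerate(feature_ids)}
        self._spos = {s: i for i, s in enumerate(sample_ids)}

    @property
    def shape(self):
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def select_samples(self, sample_ids) -> "CountMatrix":
        idx = [self._spos[s] for s in sample_ids]
        return CountMatrix(self.counts[:, idx], self.feature_ids, list(sample_ids),
                           self.feature_type)

    def select_features(self, feature_ids) -> "CountMatrix":
        idx = [self._fpos[f] for f in feature_ids]
        return CountMatrix(self.counts[idx], list(feature_ids), self.sample_ids,
                           self.feature_type)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_type: str = "mRNA") -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns), feature_type)


@dataclass
class NormalizationState:
    """Per-sample library sizes and TMM factors (geometric mean 1)."""

    library_sizes: np.ndarray
    tmm_factors: np.ndarray

    def __post_init__(self):
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.tmm_factors = np.asarray(self.tmm_factors, dtype=float)
        if np.any(self.tmm_factors <= 0):
            raise ValueError("TMM factors must be positive")

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    @classmethod
    def plain(cls, m: CountMatrix) -> "NormalizationState":
        libs = m.library_sizes()
        return cls(libs, np.ones_like(libs))


@dataclass
class FilterReport:
    n_input: int
    n_undetectable: int   # zero in every sample
    n_filtered: int       # detectable but below threshold
    n_retained: int


@dataclass
class DispersionFit:
    common: float
    per_feature: np.ndarray
    feature_ids: list


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------

def cpm(m: CountMatrix, norm: NormalizationState | None = None, log2: bool = False,
        prior: float = 0.5) -> pd.DataFrame:
    """Counts per million over effective library sizes.

    ``log2=True`` returns ``log2((count + prior) / (effective_size + 2*prior) * 1e6)``.
    """
    eff = norm.effective_sizes if norm is not None else m.library_sizes()
    if np.any(eff <= 0):
        raise ValueError("zero library size")
    if log2:
        if prior <= 0:
            raise ValueError("prior must be positive for log2-CPM")
        vals = np.log2((m.counts + prior) / (eff + 2 * prior)[None, :] * 1e6)
    else:
        vals = m.counts / eff[None, :] * 1e6
    return pd.DataFrame(vals, index=pd.Index(m.feature_ids, name="feature_id"),
                        columns=m.sample_ids)


def filter_low_counts(m: CountMatrix, min_cpm: float = 1.0,
                      min_samples: int | None = None):
    """Keep features with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    ``min_samples`` defaults to the full sample count's smallest plausible
    group (callers normally pass the smallest group size).  Returns the
    filtered matrix and a :class:`FilterReport` partitioning the input into
    undetectable (all-zero), filtered and retained features.
    """
    n_samp = len(m.sample_ids)
    if min_samples is None:
        min_samples = n_samp
    if min_samples > n_samp:
        raise ValueError("min_samples exceeds the number of samples")
    vals = cpm(m)
    keep = (vals.to_numpy() >= min_cpm).sum(axis=1) >= min_samples
    undet = m.counts.sum(axis=1) == 0
    keep &= ~undet
    report = FilterReport(
        n_input=len(m.feature_ids),
        n_undetectable=int(undet.sum()),
        n_filtered=int((~keep & ~undet).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("no features pass filtering; lower min_cpm or min_samples")
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return m.select_features(kept_ids), report


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.3, trim_a: float = 0.05) -> float:
    """Trimmed mean of M-values factor of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        warnings.warn("sample shares no co-expressed features with reference; factor set to 1")
        return 1.0
    o, r = obs[ok], ref[ok]
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    rank_m = sps.rankdata(m, method="ordinal")
    rank_a = sps.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() <= 0:
        return 1.0
    f = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return 2.0 ** f


def tmm_factors(m: CountMatrix) -> NormalizationState:
    """Trimmed-mean-of-M-values scaling factors, renormalized to geometric mean 1.

    The reference sample is the one whose 75th CPM percentile is closest to
    the cohort mean, following the usual convention.  M-values are trimmed
    30%, A-values 5%, and the remainder averaged with inverse asymptotic
    variance weights.
    """
    libs = m.library_sizes()
    if len(m.sample_ids) < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.any(libs <= 0):
        raise ValueError("every sample must have a nonzero total")
    q75 = np.array([np.percentile(m.counts[:, j] / libs[j], 75) for j in range(len(libs))])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(len(libs))
    for j in range(len(libs)):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(m.counts[:, j].astype(float), m.counts[:, ref_idx].astype(float),
                               libs[j], libs[ref_idx])
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationState(libs, factors)


# ---------------------------------------------------------------------------
# negative-binomial GLM
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-feature NB log-likelihood, summed over samples (rows = features)."""
    mu = np.maximum(mu, 1e-10)
    if phi < 1e-8:
        return (y * np.log(mu) - mu - gammaln(y + 1)).sum(axis=1)
    r = 1.0 / phi
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))).sum(axis=1)


def _fit_group_means(y: np.ndarray, t: np.ndarray, phi: float, n_iter: int = 30,
                     tol: float = 1e-10) -> np.ndarray:
    """MLE of a single NB mean rate per feature given offsets ``t`` (Fisher scoring).

    Returns per-feature rates ``lam`` with fitted means ``lam * t``.
    """
    y = np.asarray(y, dtype=float)
    tot_y = y.sum(axis=1)
    tot_t = t.sum()
    lam = (tot_y + 0.1) / tot_t
    if phi < 1e-8:
        return tot_y / tot_t
    beta = np.log(lam)
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * t[None, :]
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    lam = np.exp(beta)
    lam[tot_y == 0] = 0.0
    return lam


def _profile_loglik(y, t, group_masks, phi) -> np.ndarray:
    ll = np.zeros(y.shape[0])
    mu = np.zeros_like(y, dtype=float)
    for mask in group_masks:
        lam = _fit_group_means(y[:, mask], t[mask], phi)
        mu[:, mask] = lam[:, None] * t[mask][None, :]
    return _nb_loglik(y, mu, phi)


def nb_fit_dispersion(m: CountMatrix, groups, norm: NormalizationState | None = None,
                      prior_weight: float = 20.0, floor: float = 1e-4) -> DispersionFit:
    """Common NB dispersion by profile likelihood plus shrunk per-feature values.

    The common dispersion maximizes the summed profile likelihood over a
    coarse-then-fine grid; per-feature method-of-moments estimates are then
    shrunk toward it with a fixed prior weight (in pseudo residual degrees
    of freedom).  Everything is floored at ``floor``.
    """
    groups = np.asarray(list(groups))
    if len(groups) != len(m.sample_ids):
        raise ValueError("group labels must match samples")
    norm = norm or NormalizationState.plain(m)
    t = norm.effective_sizes
    y = m.counts.astype(float)
    levels = pd.unique(groups)
    masks = [np.asarray(groups == lev) for lev in levels]
    if max(int(mk.sum()) for mk in masks) < 2:
        raise ValueError("need at least 2 samples in some group")

    def total_ll(phi):
        return float(_profile_loglik(y, t, masks, phi).sum())

    coarse = np.concatenate([[floor], np.logspace(-3.5, 0.7, 22)])
    lls = [total_ll(p) for p in coarse]
    best = coarse[int(np.argmax(lls))]
    fine = best * np.logspace(-0.35, 0.35, 15)
    lls_f = [total_ll(p) for p in fine]
    common = float(max(fine[int(np.argmax(lls_f))], floor))
    if max(lls) > max(lls_f):
        common = float(max(best, floor))

    # per-feature method of moments on library-size-adjusted pseudo-counts
    scale = t.mean() / t
    z = y * scale[None, :]
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    df = 0.0
    for mk in masks:
        ng = int(mk.sum())
        if ng < 2:
            continue
        zm = z[:, mk]
        mean_g = zm.mean(axis=1)
        var_g = zm.var(axis=1, ddof=1)
        num += (ng - 1) * (var_g - mean_g)
        den += (ng - 1) * mean_g**2
        df += ng - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_f = np.where(den > 0, num / np.maximum(den, 1e-12), common)
    phi_f = np.clip(phi_f, 0.0, None)
    shrunk = (prior_weight * common + df * phi_f) / (prior_weight + df)
    shrunk = np.maximum(shrunk, floor)
    return DispersionFit(common, shrunk, list(m.feature_ids))


def nb_lrt(m: CountMatrix, groups, contrast: tuple | None = None,
           norm: NormalizationState | None = None,
           dispersion: DispersionFit | float | np.ndarray | None = None,
           prior_count: float = 0.5) -> pd.DataFrame:
    """Two-group NB likelihood-ratio differential expression.

    ``groups`` gives one label per sample; ``contrast = (reference, treatment)``
    selects the two levels compared (defaults to the two levels present, in
    order of appearance) and ``log2fc`` is treatment over reference.  The
    p-value is the chi-square(1) tail of twice the log-likelihood difference
    between the two-mean and one-mean fits; fold changes use prior-count
    moderated group means; FDR is Benjamini-Hochberg over all tested
    features.  Returns the DE table (feature, log2fc, mean_log2cpm, p, fdr,
    direction).
    """
    groups = np.asarray(list(groups))
    if len(groups) != len(m.sample_ids):
        raise ValueError("group labels must match samples")
    levels = list(pd.unique(groups))
    if contrast is None:
        if len(levels) != 2:
            raise ValueError("groups must have exactly 2 levels or a contrast must be given")
        contrast = (levels[0], levels[1])
    ref, trt = contrast
    for lev in contrast:
        if lev not in levels:
            raise ValueError(f"contrast level {lev!r} absent from group labels")
    sel = (groups == ref) | (groups == trt)
    y = m.counts[:, sel].astype(float)
    g = groups[sel]
    norm = norm or NormalizationState.plain(m)
    t = norm.effective_sizes[sel]
    mask_ref, mask_trt = g == ref, g == trt
    if mask_ref.sum() < 2 or mask_trt.sum() < 2:
        raise ValueError("both contrast groups need at least 2 samples")

    if dispersion is None:
        dispersion = nb_fit_dispersion(m.select_samples(
            [s for s, k in zip(m.sample_ids, sel) if k]), g)
    if isinstance(dispersion, DispersionFit):
        phi = np.asarray(dispersion.per_feature, dtype=float)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()

    # group features by (binned) dispersion to keep the fits vectorized
    ll_full = np.zeros(y.shape[0])
    ll_null = np.zeros(y.shape[0])
    bins = np.round(np.log10(np.maximum(phi, 1e-6)) * 50).astype(int)
    for b in np.unique(bins):
        idx = np.where(bins == b)[0]
        phi_b = float(np.median(phi[idx]))
        yb = y[idx]
        ll_null[idx] = _profile_loglik(yb, t, [np.ones(len(t), bool)], phi_b)
        ll_full[idx] = _profile_loglik(yb, t, [mask_ref, mask_trt], phi_b)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = sps.chi2.sf(lrt, df=1)
    bad = ~np.isfinite(lrt)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} features failed to converge; p set to 1")
        p[bad] = 1.0

    mean_ref = (y[:, mask_ref].sum(axis=1) + prior_count) / t[mask_ref].sum()
    mean_trt = (y[:, mask_trt].sum(axis=1) + prior_count) / t[mask_trt].sum()
    log2fc = np.log2(mean_trt / mean_ref)
    mean_log2cpm = np.log2((y + prior_count) / (t + 2 * prior_count)[None, :] * 1e6).mean(axis=1)
    fdr = bh_adjust(p)
    table = pd.DataFrame({
        "feature_id": m.feature_ids,
        "log2fc": log2fc,
        "mean_log2cpm": mean_log2cpm,
        "p": p,
        "fdr": fdr,
        "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
    }).set_index("feature_id")
    table.attrs["contrast"] = (ref, trt)
    return table


def select_signature(table: pd.DataFrame, fdr_max: float = 0.05,
                     min_abs_log2fc: float = 1.0, top_n: int | None = None) -> list:
    """Features passing FDR and fold-change thresholds, ranked by p ascending.

    Ties in p break by larger ``|log2fc|``, then lexicographic feature id.
    Truncated to ``top_n`` when given; a warning is emitted if fewer than
    ``top_n`` features pass.
    """
    if fdr_max <= 0 or min_abs_log2fc < 0:
        raise ValueError("thresholds must be positive")
    passing = table[(table["fdr"] <= fdr_max) & (table["log2fc"].abs() >= min_abs_log2fc)].copy()
    passing["_abs"] = passing["log2fc"].abs()
    passing = passing.sort_values(["p", "_abs", "feature_id"],
                                  ascending=[True, False, True],
                                  kind="stable")
    ids = list(passing.index)
    if top_n is not None:
        if len(ids) < top_n:
            warnings.warn(f"only {len(ids)} features pass thresholds (top_n = {top_n})")
        ids = ids[:top_n]
    if not ids:
        warnings.warn("no features pass the signature thresholds")
    return ids
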