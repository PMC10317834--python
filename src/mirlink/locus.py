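"""Locus-level expression analytics for a clustered, co-regulated miRNA locus.

Covers interval membership (midpoint rule on 1-based inclusive coordinates),
locus-wide per-sample and per-group expression summaries with between-group
rank tests, per-miRNA ribbon summaries (median/IQR per group in genomic
order), the co-expression structure of locus members with flanking features,
correlation of the locus mean against a single gene, and k-means grouping of
samples by their locus expression profiles.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, kmeans, pearson_corr, wilcoxon_rank_sum

__all__ = [
    "LocusDefinition",
    "LocusSummary",
    "ClusterAssignment",
    "assign_locus_membership",
    "locus_group_summary",
    "ribbon_summary",
    "coexpression_matrix",
    "locus_vs_gene_correlation",
    "cluster_samples",
]


@dataclass
class LocusDefinition:
    """Genomic interval, 1-based inclusive (``chr14:100,825,000-101,070,000`` style)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("locus start exceeds end")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str, name: str = "") -> "LocusDefinition":
        m = re.fullmatch(r"\s*([\w.]+):([\d,]+)-([\d,]+)\s*", text)
        if not m:
            raise ValueError(f"cannot parse locus string {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")),
                   int(m.group(3).replace(",", "")), name)


@dataclass
class LocusSummary:
    per_sample_mean: pd.Series           # mean log2-CPM over members, per sample
    group_means: pd.Series               # per group
    tests: dict                          # (group_a, group_b) -> TestResult
    fraction_lower: dict                 # (group_a, group_b) -> fraction of members
                                         # with lower mean in group_a than group_b
    members: list = field(default_factory=list)


@dataclass
class ClusterAssignment:
    labels: pd.Series                    # sample -> cluster name
    cluster_names: list                  # ordered high -> low
    contingency: pd.DataFrame            # subgroup x cluster counts
    centers: np.ndarray
    inertia: float
    test: TestResult | None = None


def assign_locus_membership(annotation: pd.DataFrame, locus: LocusDefinition) -> list:
    """Features whose midpoint lies inside the locus (boundaries inclusive).

    ``annotation`` is indexed by feature id with ``chrom``/``start``/``end``
    columns in 1-based inclusive coordinates.  Features with missing
    coordinates are excluded with a warning.  Members are returned in
    genomic (start) order.
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    ann = annotation
    bad = ann[["chrom", "start", "end"]].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} features lack coordinates and are excluded")
        ann = ann[~bad]
    mid = (ann["start"].astype(float) + ann["end"].astype(float)) / 2.0
    member = (ann["chrom"] == locus.chrom) & (mid >= locus.start) & (mid <= locus.end)
    sel = ann[member].sort_values(["start", "end"], kind="stable")
    return list(sel.index)


def locus_group_summary(log2cpm: pd.DataFrame, members, groups: pd.Series,
                        mode: str = "auto") -> LocusSummary:
    """Locus-wide expression summary by sample group.

    The locus signal per sample is the mean log2-CPM over member features.
    Every unordered pair of groups is compared with the Wilcoxon rank-sum
    test (exact where feasible), and a per-member direction tally gives the
    fraction of members whose mean is lower in the first group of each pair.
    """
    members = [f for f in members if f in log2cpm.index]
    if not members:
        raise ValueError("no locus members present in the expression matrix")
    sub = log2cpm.loc[members, groups.index]
    per_sample = sub.mean(axis=0)
    per_sample.name = "locus_mean_log2cpm"
    group_means = per_sample.groupby(groups).mean()
    levels = list(pd.unique(groups))
    tests = {}
    frac = {}
    member_group_means = sub.T.groupby(groups).mean().T  # members x groups
    for a, b in itertools.combinations(levels, 2):
        tests[(a, b)] = wilcoxon_rank_sum(per_sample[groups == a], per_sample[groups == b],
                                          mode=mode)
        frac[(a, b)] = float((member_group_means[a] < member_group_means[b]).mean())
        frac[(b, a)] = float((member_group_means[b] < member_group_means[a]).mean())
    return LocusSummary(per_sample, group_means, tests, frac, members)


def ribbon_summary(log2cpm: pd.DataFrame, members, groups: pd.Series,
                   annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Median and interquartile range per member miRNA and group.

    Rows are ordered 5'-3' by genomic start when ``annotation`` is given
    (otherwise in the order supplied).  Quantiles use linear interpolation.
    """
    members = list(members)
    if annotation is not None:
        order = annotation.loc[members].sort_values(["start", "end"], kind="stable").index
        members = list(order)
    rows = []
    for rank, fid in enumerate(members):
        vals = log2cpm.loc[fid, groups.index]
        for g in pd.unique(groups):
            v = vals[groups == g].to_numpy(dtype=float)
            rows.append({
                "feature_id": fid, "group": g, "genomic_order": rank,
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            })
    return pd.DataFrame(rows)


def coexpression_matrix(log2cpm: pd.DataFrame, annotation: pd.DataFrame,
                        locus: LocusDefinition, window: int = 500_000):
    """All-pairs Pearson correlation of locus members plus flanking features.

    Flanking features lie on the locus chromosome within ``window`` bp of
    either boundary (midpoint rule).  Features are ordered genomically.
    Returns ``(r, p_adj, member_flags)``: the correlation matrix with unit
    diagonal, BH-adjusted p-values over the upper triangle, and a boolean
    Series marking locus members.  Degenerate (zero-variance) features keep
    their row with undefined (NaN) entries.
    """
    members = assign_locus_membership(annotation, locus)
    expanded = LocusDefinition(locus.chrom, max(1, locus.start - window),
                               locus.end + window, locus.name)
    in_window = assign_locus_membership(annotation, expanded)
    feats = [f for f in in_window if f in log2cpm.index]
    if len(feats) < 2:
        raise ValueError("need at least 2 features in the locus window")
    X = log2cpm.loc[feats].to_numpy(dtype=float)
    n = X.shape[1]
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate features in co-expression matrix")
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1))
    denom[degenerate] = np.nan
    R = (Xc @ Xc.T) / np.outer(denom, denom)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    from scipy import stats as sps
    P = 2.0 * sps.t.sf(np.abs(t), n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    iu = np.triu_indices(len(feats), k=1)
    flat = P[iu]
    ok = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = bh_adjust(flat[ok])
    Padj = np.full_like(P, np.nan)
    Padj[iu] = adj
    Padj.T[iu] = adj
    np.fill_diagonal(Padj, 0.0)
    r_df = pd.DataFrame(R, index=feats, columns=feats)
    p_df = pd.DataFrame(Padj, index=feats, columns=feats)
    flags = pd.Series([f in set(members) for f in feats], index=feats, name="is_member")
    return r_df, p_df, flags


def locus_vs_gene_correlation(locus_mean: pd.Series, gene: pd.Series) -> TestResult:
    """Pearson correlation of the locus per-sample mean against one gene."""
    common = locus_mean.index.intersection(gene.index)
    if len(common) != len(locus_mean):
        raise ValueError("locus mean and gene vector must align by sample")
    return pearson_corr(locus_mean[common].to_numpy(), gene[common].to_numpy())


_CLUSTER_NAMES3 = ["high", "intermediate", "low"]


def cluster_samples(log2cpm: pd.DataFrame, members, groups: pd.Series, k: int = 3,
                    seed: int = 0, restarts: int = 10, test: bool = False) -> ClusterAssignment:
    """k-means grouping of samples by z-scored locus member profiles.

    Each member miRNA is z-scored across samples before clustering so highly
    expressed members do not dominate the Euclidean metric.  Clusters are
    named ``high``/``intermediate``/``low`` for k = 3 (``cluster1..k``
    otherwise), ordered by descending mean locus expression, and a
    subgroup x cluster contingency table is returned.  ``test=True`` adds a
    chi-square independence test of that table (exact tests beyond 2x2 are
    not provided).
    """
    members = [f for f in members if f in log2cpm.index]
    if not members:
        raise ValueError("no locus members present in the expression matrix")
    sub = log2cpm.loc[members, groups.index]
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    points = z.T  # samples x members
    km = kmeans(points, k=k, restarts=restarts, seed=seed)
    # order clusters by unscaled mean locus expression, high first
    locus_mean = sub.mean(axis=0).to_numpy()
    order = np.argsort([-locus_mean[km.labels == j].mean() if (km.labels == j).any() else np.inf
                        for j in range(k)], kind="stable")
    names = _CLUSTER_NAMES3 if k == 3 else [f"cluster{j + 1}" for j in range(k)]
    name_of = {int(cl): names[pos] for pos, cl in enumerate(order)}
    labels = pd.Series([name_of[int(l)] for l in km.labels], index=groups.index,
                       name="cluster")
    contingency = pd.crosstab(groups, labels).reindex(columns=names, fill_value=0)
    result = None
    if test:
        from scipy import stats as sps
        chi2, p, dof, _ = sps.chi2_contingency(contingency.to_numpy())
        result = TestResult(float(chi2), float(p), "chi2-contingency",
                            tuple(contingency.shape), extra={"dof": int(dof)})
    return ClusterAssignment(labels, names, contingency, km.centers, km.inertia, result)
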