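"""Resampling test for enrichment of database-supported miRNA:mRNA interactions.

Given a miRNA set and an mRNA set (for example, a co-regulated locus cluster
and a differential-expression signature), the observed statistic is the
number of distinct database pairs joining them.  The null distribution is
built by drawing B size-matched random sets (uniform, without replacement)
from the expressed miRNA and mRNA universes and re-counting.

Two p-values are reported: the one-sample Student t of the null sample
against the observed value (the construction used in the emulated analysis,
with alternative "null mean less than observed") and the empirical
``p = (1 + #{null >= observed}) / (B + 1)``.  The empirical p is the
recommended statistic: the t construction's standard error shrinks with B,
making it anti-conservative for large B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import TestResult, one_sample_t

__all__ = [
    "ResamplingConfig",
    "EnrichmentResult",
    "count_db_interactions",
    "sample_null_counts",
    "enrichment_test",
    "enrichment_analysis",
]


@dataclass
class ResamplingConfig:
    n_mirna_draw: int
    n_mrna_draw: int
    mirna_universe: list
    mrna_universe: list
    B: int = 50_000
    seed: int = 0

    def __post_init__(self):
        self.mirna_universe = list(self.mirna_universe)
        self.mrna_universe = list(self.mrna_universe)
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.n_mirna_draw > len(self.mirna_universe):
            raise ValueError("miRNA draw size exceeds universe size")
        if self.n_mrna_draw > len(self.mrna_universe):
            raise ValueError("mRNA draw size exceeds universe size")
        if self.n_mirna_draw < 1 or self.n_mrna_draw < 1:
            raise ValueError("draw sizes must be >= 1")


@dataclass
class EnrichmentResult:
    observed_count: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    t_statistic: float
    p_t: float
    p_empirical: float
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def _union_pairs(dbs) -> set:
    pairs = set()
    for db in dbs:
        pairs |= db.pair_set()
    return pairs


def count_db_interactions(mirnas, genes, dbs) -> int:
    """Distinct database pairs (union over databases) joining the two sets."""
    mirnas = {str(m).casefold() for m in mirnas}
    genes = {str(g).casefold() for g in genes}
    if not mirnas or not genes:
        raise ValueError("both feature sets must be nonempty")
    pairs = _union_pairs(dbs)
    if not pairs:
        warnings.warn("empty database union")
        return 0
    return sum(1 for m, g in pairs if m in mirnas and g in genes)


def sample_null_counts(cfg: ResamplingConfig, dbs, chunk: int = 512) -> np.ndarray:
    """B database-pair counts over random size-matched miRNA/mRNA sets.

    Each draw samples ``n_mirna_draw`` miRNAs and ``n_mrna_draw`` mRNAs
    uniformly without replacement from their universes and counts the
    distinct database pairs joining them.  Deterministic under ``cfg.seed``.
    Draws are vectorized in chunks: a pair contributes when both of its
    endpoints are selected, so each chunk reduces to boolean gathers over
    the database's index arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    M = len(cfg.mirna_universe)
    G = len(cfg.mrna_universe)
    mpos = {str(m).casefold(): i for i, m in enumerate(cfg.mirna_universe)}
    gpos = {str(g).casefold(): j for j, g in enumerate(cfg.mrna_universe)}
    mi, gi = [], []
    for m, g in sorted(_union_pairs(dbs)):
        if m in mpos and g in gpos:
            mi.append(mpos[m])
            gi.append(gpos[g])
    mi = np.asarray(mi, dtype=np.int64)
    gi = np.asarray(gi, dtype=np.int64)
    out = np.empty(cfg.B, dtype=np.int64)
    done = 0
    while done < cfg.B:
        c = min(chunk, cfg.B - done)
        # uniform k-subsets via argpartition of random keys
        sel_m = np.zeros((c, M), dtype=bool)
        keys = rng.random((c, M))
        idx = np.argpartition(keys, cfg.n_mirna_draw - 1, axis=1)[:, : cfg.n_mirna_draw]
        np.put_along_axis(sel_m, idx, True, axis=1)
        sel_g = np.zeros((c, G), dtype=bool)
        keys = rng.random((c, G))
        idx = np.argpartition(keys, cfg.n_mrna_draw - 1, axis=1)[:, : cfg.n_mrna_draw]
        np.put_along_axis(sel_g, idx, True, axis=1)
        if mi.size:
            out[done: done + c] = (sel_m[:, mi] & sel_g[:, gi]).sum(axis=1)
        else:
            out[done: done + c] = 0
        done += c
    return out


def enrichment_test(observed: int, null_counts) -> EnrichmentResult:
    """Compare an observed pair count against its resampling null.

    ``p_t`` is the one-sided one-sample t of the null counts against
    mu = observed (alternative: null mean less than observed).  A
    zero-variance null flags the result degenerate; ``p_empirical`` is then
    the authoritative p-value.
    """
    null_counts = np.asarray(null_counts)
    B = null_counts.size
    if B < 2:
        raise ValueError("need at least 2 null counts")
    p_emp = (1.0 + int(np.sum(null_counts >= observed))) / (B + 1.0)
    tr = one_sample_t(null_counts.astype(float), mu=float(observed), alternative="less")
    return EnrichmentResult(
        observed_count=int(observed),
        null_counts=null_counts,
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std(ddof=1)),
        t_statistic=float(tr.statistic) if not tr.degenerate else float("nan"),
        p_t=float(tr.p_value) if not tr.degenerate else float("nan"),
        p_empirical=float(p_emp),
        degenerate=tr.degenerate,
        extra={"B": int(B)},
    )


def enrichment_analysis(mirnas, genes, dbs, cfg: ResamplingConfig) -> EnrichmentResult:
    """Observed count plus resampling null plus test, in one call."""
    observed = count_db_interactions(mirnas, genes, dbs)
    null = sample_null_counts(cfg, dbs)
    res = enrichment_test(observed, null)
    res.extra["seed"] = cfg.seed
    return res
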