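"""miRNA:mRNA anti-correlation network construction and export.

An edge joins a miRNA and an mRNA when their expression profiles are
significantly negatively correlated (Pearson, BH-adjusted across all tested
pairs) AND the pair is listed in at least ``min_sources`` target-interaction
databases.  The resulting object is a bipartite :mod:`networkx` graph whose
edges carry the correlation, adjusted p and supporting database sources, and
whose nodes carry the feature type and differential-expression log2FC.

Identifier matching against databases is an exact string match after
case-folding; no alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "TargetDatabase",
    "correlate_pairs",
    "filter_negative_significant",
    "intersect_with_databases",
    "build_network",
    "degree_summary",
    "fraction_of_signature_targeted",
    "export_network",
    "read_network_tsv",
]


class TargetDatabase:
    """Directed (miRNA -> gene) putative interactions with source labels.

    ``entries`` is a DataFrame with columns ``mirna_id``, ``gene_id``,
    ``source`` and optional ``score`` in [0, 100].  Duplicate
    (miRNA, gene, source) triples are rejected.  Pair membership queries are
    case-folded.
    """

    def __init__(self, entries: pd.DataFrame, name: str = "db"):
        entries = entries.copy()
        required = ["mirna_id", "gene_id", "source"]
        for col in required:
            if col not in entries.columns:
                raise ValueError(f"database entries need a {col!r} column")
        if "score" not in entries.columns:
            entries["score"] = np.nan
        for col in ("mirna_id", "gene_id"):
            entries[col] = entries[col].astype(str)
            if (entries[col].str.len() == 0).any():
                raise ValueError(f"empty {col} in database entries")
        dup = entries.duplicated(subset=["mirna_id", "gene_id", "source"])
        if dup.any():
            raise ValueError("duplicate (mirna, gene, source) triples in database")
        scores = entries["score"].dropna()
        if ((scores < 0) | (scores > 100)).any():
            raise ValueError("scores must lie in [0, 100]")
        self.entries = entries.reset_index(drop=True)
        self.name = name
        self._pairs = {(m.casefold(), g.casefold())
                       for m, g in zip(entries["mirna_id"], entries["gene_id"])}

    def __len__(self) -> int:
        return len(self.entries)

    def pair_set(self) -> set:
        """Distinct (miRNA, gene) pairs, case-folded."""
        return set(self._pairs)

    def contains(self, mirna: str, gene: str) -> bool:
        return (mirna.casefold(), gene.casefold()) in self._pairs

    def lookup(self, mirna: str, gene: str) -> pd.DataFrame:
        m, g = mirna.casefold(), gene.casefold()
        ent = self.entries
        mask = (ent["mirna_id"].str.casefold() == m) & (ent["gene_id"].str.casefold() == g)
        return ent[mask]

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "TargetDatabase":
        df = pd.read_csv(path, sep="\t")
        return cls(df, name=name or Path(path).stem)


def correlate_pairs(mirna_log2cpm: pd.DataFrame, mrna_log2cpm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every (miRNA, mRNA) pair across shared samples.

    Returns a long-form table (mirna_id, gene_id, r, p_raw, p_adj) with the
    BH adjustment computed jointly over all tested pairs.  Degenerate
    (zero-variance) features are skipped with a warning.  Sample columns
    must match between the two matrices.
    """
    if list(mirna_log2cpm.columns) != list(mrna_log2cpm.columns):
        extra_m = set(mirna_log2cpm.columns) - set(mrna_log2cpm.columns)
        extra_g = set(mrna_log2cpm.columns) - set(mirna_log2cpm.columns)
        if extra_m or extra_g:
            raise ValueError(f"sample mismatch between matrices: "
                             f"miRNA-only={sorted(extra_m)} mRNA-only={sorted(extra_g)}")
        mrna_log2cpm = mrna_log2cpm[mirna_log2cpm.columns]
    n = mirna_log2cpm.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    A = mirna_log2cpm.to_numpy(dtype=float)
    B = mrna_log2cpm.to_numpy(dtype=float)
    ok_a = A.std(axis=1) > 0
    ok_b = B.std(axis=1) > 0
    if (~ok_a).any() or (~ok_b).any():
        warnings.warn(f"skipping {int((~ok_a).sum())} degenerate miRNAs and "
                      f"{int((~ok_b).sum())} degenerate mRNAs")
    mirna_ids = np.asarray(mirna_log2cpm.index)[ok_a]
    gene_ids = np.asarray(mrna_log2cpm.index)[ok_b]
    A = A[ok_a]
    B = B[ok_b]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    Ac /= np.sqrt((Ac**2).sum(axis=1, keepdims=True))
    Bc /= np.sqrt((Bc**2).sum(axis=1, keepdims=True))
    R = np.clip(Ac @ Bc.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    P = 2.0 * sps.t.sf(np.abs(t), n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    flat_r = R.ravel()
    flat_p = P.ravel()
    pairs = pd.DataFrame({
        "mirna_id": np.repeat(mirna_ids, len(gene_ids)),
        "gene_id": np.tile(gene_ids, len(mirna_ids)),
        "r": flat_r,
        "p_raw": flat_p,
        "p_adj": bh_adjust(flat_p),
    })
    return pairs


def filter_negative_significant(pairs: pd.DataFrame, p_adj_max: float = 0.05) -> pd.DataFrame:
    """Pairs with r < 0 and BH-adjusted p <= ``p_adj_max`` (inclusive)."""
    if not 0 < p_adj_max <= 1:
        raise ValueError("p_adj_max must lie in (0, 1]")
    return pairs[(pairs["r"] < 0) & (pairs["p_adj"] <= p_adj_max)].reset_index(drop=True)


def intersect_with_databases(pairs: pd.DataFrame, dbs, min_sources: int = 1) -> pd.DataFrame:
    """Keep pairs present in at least ``min_sources`` databases.

    Adds ``n_databases``, ``sources`` (semicolon-joined labels across all
    supporting entries) and ``best_score`` columns.
    """
    dbs = list(dbs)
    if not dbs:
        raise ValueError("empty database list")
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    n_db = np.zeros(len(pairs), dtype=int)
    sources = [[] for _ in range(len(pairs))]
    best = np.full(len(pairs), np.nan)
    keys = list(zip(pairs["mirna_id"].str.casefold(), pairs["gene_id"].str.casefold()))
    for db in dbs:
        pset = db.pair_set()
        # index entries of this db once
        ent = db.entries
        tab = {}
        for m, g, s, sc in zip(ent["mirna_id"].str.casefold(), ent["gene_id"].str.casefold(),
                               ent["source"], ent["score"]):
            tab.setdefault((m, g), []).append((s, sc))
        for i, key in enumerate(keys):
            if key in pset:
                n_db[i] += 1
                for s, sc in tab[key]:
                    sources[i].append(str(s))
                    if not np.isnan(sc) and (np.isnan(best[i]) or sc > best[i]):
                        best[i] = sc
    out = pairs.copy().reset_index(drop=True)
    out["n_databases"] = n_db
    out["sources"] = [";".join(s) for s in sources]
    out["best_score"] = best
    return out[out["n_databases"] >= min_sources].reset_index(drop=True)


def build_network(annotated_pairs: pd.DataFrame, de_tables: dict | None = None) -> nx.Graph:
    """Bipartite miRNA:mRNA graph from annotated (database-supported) pairs.

    ``de_tables`` maps feature type (``"miRNA"``/``"mRNA"``) to a DE table
    indexed by feature id; node ``log2fc`` attributes come from there
    (missing features get NaN with a warning).  Duplicate input pairs
    collapse to a single edge; edge weight is ``|r|``.
    """
    de_tables = de_tables or {}
    g = nx.Graph()
    missing = set()

    def lfc(kind, fid):
        table = de_tables.get(kind)
        if table is not None and fid in table.index:
            return float(table.loc[fid, "log2fc"])
        missing.add(fid)
        return float("nan")

    for row in annotated_pairs.itertuples(index=False):
        m, t = str(row.mirna_id), str(row.gene_id)
        if not g.has_node(m):
            g.add_node(m, feature_type="miRNA", bipartite=0, log2fc=lfc("miRNA", m))
        if not g.has_node(t):
            g.add_node(t, feature_type="mRNA", bipartite=1, log2fc=lfc("mRNA", t))
        g.add_edge(m, t, r=float(row.r), p_adj=float(row.p_adj), weight=abs(float(row.r)),
                   sources=str(getattr(row, "sources", "")))
    if missing and de_tables:
        warnings.warn(f"{len(missing)} network nodes lack a DE attribute (log2fc = NaN)")
    return g


def degree_summary(net: nx.Graph):
    """Ranked per-node edge counts, split by feature type.

    Returns ``(mirna_table, mrna_table)``; each is sorted by degree
    descending with lexicographic tie-break, plus an ``is_singleton`` flag
    so degree-1 nodes can be summarized as one bucket.
    """
    rows = {"miRNA": [], "mRNA": []}
    for node, data in net.nodes(data=True):
        rows[data["feature_type"]].append((node, net.degree(node)))
    out = []
    for kind in ("miRNA", "mRNA"):
        df = pd.DataFrame(rows[kind], columns=["feature_id", "degree"])
        df = df.sort_values(["degree", "feature_id"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
        df["is_singleton"] = df["degree"] == 1
        out.append(df)
    return tuple(out)


def fraction_of_signature_targeted(net: nx.Graph, signature) -> tuple:
    """How many signature mRNAs have at least one network edge.

    Returns ``(covered_count, fraction)`` with the fraction over the full
    signature length.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("signature must be nonempty")
    nodes = {n.casefold(): n for n, d in net.nodes(data=True) if d["feature_type"] == "mRNA"}
    covered = 0
    for fid in signature:
        node = nodes.get(str(fid).casefold())
        if node is not None and net.degree(node) >= 1:
            covered += 1
    return covered, covered / len(signature)


_EDGE_COLUMNS = ["mirna_id", "gene_id", "r", "p_adj", "weight", "sources"]


def export_network(net: nx.Graph, fmt: str, path) -> None:
    """Write the network as SIF, GraphML or an edge TSV.

    SIF lines read ``mirna<TAB>targets<TAB>gene``.  GraphML keeps node and
    edge attributes.  The edge TSV round-trips through
    :func:`read_network_tsv`.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for m, t, _ in _iter_edges(net):
                fh.write(f"{m}\ttargets\t{t}\n")
    elif fmt == "graphml":
        g = net.copy()
        for _, data in g.nodes(data=True):
            if isinstance(data.get("log2fc"), float) and np.isnan(data["log2fc"]):
                data["log2fc"] = "NA"
        nx.write_graphml(g, path)
    elif fmt == "edge-tsv":
        rows = [{
            "mirna_id": m, "gene_id": t, "r": d.get("r"), "p_adj": d.get("p_adj"),
            "weight": d.get("weight"), "sources": d.get("sources", ""),
        } for m, t, d in _iter_edges(net)]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _iter_edges(net: nx.Graph):
    for u, v, d in sorted(net.edges(data=True)):
        if net.nodes[u]["feature_type"] == "miRNA":
            yield u, v, d
        else:
            yield v, u, d


def read_network_tsv(path) -> nx.Graph:
    """Rebuild a network from an edge TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"sources": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.mirna_id, feature_type="miRNA", bipartite=0)
        g.add_node(row.gene_id, feature_type="mRNA", bipartite=1)
        g.add_edge(row.mirna_id, row.gene_id, r=float(row.r), p_adj=float(row.p_adj),
                   weight=float(row.weight), sources=str(row.sources))
    return g
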