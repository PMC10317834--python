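"""End-to-end orchestration: filter -> normalize -> DE -> locus -> network -> enrichment.

:func:`run_pipeline` drives the whole analysis from a :class:`PipelineConfig`
whose inputs are either file paths or in-memory objects (a
:class:`~mirlink.synthetic.SyntheticDataset` plugs in directly).  Every stage
writes its plain-text outputs under the configured output directory, and the
run finishes with a manifest recording the config snapshot, package version,
seeds, per-stage row counts and a checksum for every file written, so reruns
with the same seed are bitwise comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .diffexpr import (CountMatrix, NormalizationState, cpm, filter_low_counts,
                       nb_fit_dispersion, nb_lrt, select_signature, tmm_factors)
from .enrichment import ResamplingConfig, enrichment_analysis
from .locus import (LocusDefinition, assign_locus_membership, cluster_samples,
                    coexpression_matrix, locus_group_summary, locus_vs_gene_correlation,
                    ribbon_summary)
from .network import (build_network, correlate_pairs, degree_summary, export_network,
                      filter_negative_significant, fraction_of_signature_targeted,
                      intersect_with_databases)
from .stats import pca

logger = logging.getLogger("mirlink.pipeline")

__all__ = ["Contrast", "PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class Contrast:
    """A two-group comparison; groups may merge several metadata labels."""

    name: str
    reference: tuple
    treatment: tuple

    def collapse(self, groups: pd.Series) -> pd.Series:
        lab = pd.Series("__other__", index=groups.index)
        lab[groups.isin(self.reference)] = "reference"
        lab[groups.isin(self.treatment)] = "treatment"
        return lab


@dataclass
class PipelineConfig:
    """Paths (or in-memory objects), thresholds and stage parameters."""

    mrna_counts: object = None          # path or CountMatrix
    mirna_counts: object = None
    metadata: object = None             # path or Series
    annotation: object = None           # path or DataFrame
    databases: tuple = ()               # paths or TargetDatabase objects
    locus: object = None                # "chr:start-end", path or LocusDefinition
    outdir: str = "mirlink_out"
    contrasts: tuple = ()               # Contrast objects; first is primary
    fdr_max: float = 0.05
    min_abs_log2fc: float = 1.0
    top_n: int = 200
    pair_p_adj_max: float = 0.05
    min_sources: int = 1
    resample_B: int = 50_000
    seed: int = 0
    min_cpm: float = 1.0
    min_samples: int | None = None      # default: smallest group size
    locus_k: int = 3
    flank_window: int = 500_000
    network_mirnas: str = "locus"       # "locus" (cluster members) or "de" (DEM signature)
    exclude_locus_from_null: bool = False

    def validate(self, groups: pd.Series) -> None:
        if not 0 < self.fdr_max <= 1 or not 0 < self.pair_p_adj_max <= 1:
            raise ValueError("FDR thresholds must lie in (0, 1]")
        if self.min_abs_log2fc < 0 or self.top_n < 1 or self.min_sources < 1:
            raise ValueError("invalid threshold configuration")
        if self.resample_B < 1:
            raise ValueError("resample_B must be >= 1")
        if self.network_mirnas not in ("locus", "de"):
            raise ValueError("network_mirnas must be 'locus' or 'de'")
        levels = set(groups.unique())
        for c in self.contrasts:
            missing = (set(c.reference) | set(c.treatment)) - levels
            if missing:
                raise ValueError(f"contrast {c.name!r}: labels {sorted(missing)} "
                                 "absent from metadata")


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)      # path -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    from .network import TargetDatabase
    mrna = cfg.mrna_counts if isinstance(cfg.mrna_counts, CountMatrix) else \
        mio.read_counts(cfg.mrna_counts, feature_type="mRNA")
    mirna = cfg.mirna_counts if isinstance(cfg.mirna_counts, CountMatrix) else \
        mio.read_counts(cfg.mirna_counts, feature_type="miRNA")
    meta = cfg.metadata if isinstance(cfg.metadata, pd.Series) else \
        mio.read_metadata_tsv(cfg.metadata)
    ann = cfg.annotation if isinstance(cfg.annotation, pd.DataFrame) else \
        mio.read_bed_annotation(cfg.annotation)
    dbs = [db if isinstance(db, TargetDatabase) else TargetDatabase.from_tsv(db)
           for db in cfg.databases]
    locus = cfg.locus if isinstance(cfg.locus, LocusDefinition) else mio.read_locus(cfg.locus)
    return mrna, mirna, meta, ann, dbs, locus


def _volcano_table(det: pd.DataFrame, fdr_max: float, min_lfc: float) -> pd.DataFrame:
    out = det.copy()
    dark = (out["fdr"] <= fdr_max) & (out["log2fc"].abs() >= min_lfc)
    light = (out["p"] <= 0.05) & (out["log2fc"].abs() >= min_lfc) & ~dark
    out["category"] = np.where(dark, "dark", np.where(light, "light", "ns"))
    return out


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the run manifest."""
    mrna, mirna, meta, ann, dbs, locus = _load_inputs(cfg)
    for m in (mrna, mirna):
        missing = set(meta.index) - set(m.sample_ids)
        if missing:
            raise ValueError(f"samples in metadata missing from {m.feature_type} "
                             f"counts: {sorted(missing)}")
    if not cfg.contrasts:
        raise ValueError("at least one contrast is required")
    cfg.validate(meta)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={k: str(v) for k, v in asdict(cfg).items()},
                           version=__version__, seed=cfg.seed)
    counts = manifest.stage_counts
    written = []

    def emit(name, writer):
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    groups = meta
    mrna = mrna.select_samples(list(meta.index))
    mirna = mirna.select_samples(list(meta.index))
    min_samples = cfg.min_samples or int(groups.value_counts().min())

    # --- stage: filter + normalize -------------------------------------
    stage = "filter"
    try:
        mrna_f, rep_m = filter_low_counts(mrna, cfg.min_cpm, min_samples)
        mirna_f, rep_mi = filter_low_counts(mirna, cfg.min_cpm, min_samples)
        counts["mrna_filter"] = vars(rep_m)
        counts["mirna_filter"] = vars(rep_mi)
        norm_m = tmm_factors(mrna_f)
        norm_mi = tmm_factors(mirna_f)
        log2cpm_m = cpm(mrna_f, norm_m, log2=True)
        log2cpm_mi = cpm(mirna_f, norm_mi, log2=True)
        logger.info("filter: mRNA %s, miRNA %s", vars(rep_m), vars(rep_mi))

        # --- stage: PCA + DE per contrast -------------------------------
        stage = "diffexpr"
        de_tables = {}
        for kind, mat, norm, l2 in (("mRNA", mrna_f, norm_m, log2cpm_m),
                                    ("miRNA", mirna_f, norm_mi, log2cpm_mi)):
            pres = pca(l2.T.to_numpy(), n_components=min(5, len(meta) - 1))
            scores = pd.DataFrame(pres.scores, index=meta.index,
                                  columns=[f"PC{i+1}" for i in range(pres.scores.shape[1])])
            scores["group"] = meta
            emit(f"pca_{kind.lower()}.tsv", lambda p, s=scores: s.to_csv(p, sep="\t"))
            for con in cfg.contrasts:
                lab = con.collapse(meta)
                keep = lab != "__other__"
                sub = mat.select_samples(list(meta.index[keep]))
                sub_norm = NormalizationState(norm.library_sizes[keep.to_numpy()],
                                              norm.tmm_factors[keep.to_numpy()])
                disp = nb_fit_dispersion(sub, lab[keep], sub_norm)
                det = nb_lrt(sub, lab[keep], contrast=("reference", "treatment"),
                             norm=sub_norm, dispersion=disp)
                det.attrs["contrast"] = con.name
                de_tables[(kind, con.name)] = det
                vol = _volcano_table(det, cfg.fdr_max, cfg.min_abs_log2fc)
                emit(f"de_{kind.lower()}_{con.name}.tsv",
                     lambda p, v=vol: v.to_csv(p, sep="\t"))
                counts[f"de_{kind}_{con.name}"] = {
                    "tested": int(len(det)),
                    "significant": int(((det.fdr <= cfg.fdr_max)
                                        & (det.log2fc.abs() >= cfg.min_abs_log2fc)).sum()),
                }

        primary = cfg.contrasts[0]
        det_mrna = de_tables[("mRNA", primary.name)]
        det_mirna = de_tables[("miRNA", primary.name)]
        signature = select_signature(det_mrna, cfg.fdr_max, cfg.min_abs_log2fc, cfg.top_n)
        counts["signature_size"] = len(signature)

        # --- stage: locus analysis ---------------------------------------
        stage = "locus"
        members = [f for f in assign_locus_membership(ann, locus)
                   if f in log2cpm_mi.index]
        counts["locus_members_expressed"] = len(members)
        summary = locus_group_summary(log2cpm_mi, members, groups)
        emit("locus_per_sample.tsv",
             lambda p: summary.per_sample_mean.rename_axis("sample_id").to_csv(p, sep="\t"))
        rows = [{"group_a": a, "group_b": b, "statistic": t.statistic, "p": t.p_value,
                 "method": t.method, "fraction_lower_a": summary.fraction_lower[(a, b)]}
                for (a, b), t in summary.tests.items()]
        emit("locus_group_tests.tsv",
             lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
        ribbon = ribbon_summary(log2cpm_mi, members, groups, ann)
        emit("locus_ribbon.tsv", lambda p: ribbon.to_csv(p, sep="\t", index=False))
        both_l2 = pd.concat([log2cpm_mi, log2cpm_m])
        r_df, p_df, flags = coexpression_matrix(both_l2, ann, locus, cfg.flank_window)
        emit("locus_coexpression_r.tsv", lambda p: r_df.to_csv(p, sep="\t"))
        emit("locus_coexpression_padj.tsv", lambda p: p_df.to_csv(p, sep="\t"))
        clus = cluster_samples(log2cpm_mi, members, groups, k=cfg.locus_k, seed=cfg.seed)
        emit("locus_clusters.tsv", lambda p: clus.labels.rename_axis("sample_id")
             .to_csv(p, sep="\t"))
        emit("locus_contingency.tsv", lambda p: clus.contingency.to_csv(p, sep="\t"))

        # --- stage: network ----------------------------------------------
        stage = "network"
        if cfg.network_mirnas == "locus":
            net_mirnas = members
        else:
            net_mirnas = select_signature(det_mirna, cfg.fdr_max, cfg.min_abs_log2fc, None)
        if not net_mirnas or not signature:
            raise ValueError("empty miRNA set or mRNA signature for the network stage")
        pairs = correlate_pairs(log2cpm_mi.loc[net_mirnas], log2cpm_m.loc[signature])
        counts["pairs_tested"] = int(len(pairs))
        neg = filter_negative_significant(pairs, cfg.pair_p_adj_max)
        counts["pairs_negative_significant"] = int(len(neg))
        supported = intersect_with_databases(neg, dbs, cfg.min_sources)
        counts["pairs_database_supported"] = int(len(supported))
        emit("network_pairs.tsv", lambda p: supported.to_csv(p, sep="\t", index=False))
        net = build_network(supported, {"miRNA": det_mirna, "mRNA": det_mrna})
        counts["network_edges"] = net.number_of_edges()
        emit("network.sif", lambda p: export_network(net, "sif", p))
        emit("network.graphml", lambda p: export_network(net, "graphml", p))
        emit("network_edges.tsv", lambda p: export_network(net, "edge-tsv", p))
        deg_mi, deg_g = degree_summary(net)
        emit("network_degree_mirna.tsv", lambda p: deg_mi.to_csv(p, sep="\t", index=False))
        emit("network_degree_mrna.tsv", lambda p: deg_g.to_csv(p, sep="\t", index=False))
        covered, fraction = fraction_of_signature_targeted(net, signature)
        counts["signature_covered"] = covered
        counts["signature_covered_fraction"] = fraction

        # --- stage: enrichment ---------------------------------------------
        stage = "enrichment"
        mirna_universe = list(log2cpm_mi.index)
        if cfg.exclude_locus_from_null:
            mirna_universe = [m for m in mirna_universe if m not in set(members)]
        rcfg = ResamplingConfig(
            n_mirna_draw=len(net_mirnas), n_mrna_draw=len(signature),
            mirna_universe=mirna_universe, mrna_universe=list(log2cpm_m.index),
            B=cfg.resample_B, seed=cfg.seed)
        enr = enrichment_analysis(net_mirnas, signature, dbs, rcfg)
        counts["enrichment"] = {
            "observed": enr.observed_count, "null_mean": enr.null_mean,
            "p_t": enr.p_t, "p_empirical": enr.p_empirical,
        }
        report = pd.DataFrame([{
            "observed": enr.observed_count, "B": enr.extra["B"],
            "null_mean": enr.null_mean, "null_sd": enr.null_sd,
            "t": enr.t_statistic, "p_t": enr.p_t, "p_empirical": enr.p_empirical,
            "seed": cfg.seed,
        }])
        emit("enrichment.tsv", lambda p: report.to_csv(p, sep="\t", index=False))
        hist = pd.Series(enr.null_counts).value_counts().sort_index()
        emit("enrichment_null_histogram.tsv",
             lambda p: hist.rename("draws").rename_axis("interactions").to_csv(p, sep="\t"))
    except Exception as exc:
        manifest.stage_counts["failed_stage"] = stage
        for path in written:
            manifest.files[str(path.relative_to(outdir))] = _sha256(path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in written:
        manifest.files[str(path.relative_to(outdir))] = _sha256(path)
    manifest.to_json(outdir / "manifest.json")
    return manifest
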