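"""Readers and writers for the plain-text formats the pipeline consumes.

Counts as TSV (features x samples, header row of sample ids) or MatrixMarket
coordinate files with sibling ``.rows``/``.cols`` id lists; sample metadata
and target databases as TSV; genomic annotation as 6-column BED.  BED is
0-based half-open on disk and converted to the package's internal 1-based
inclusive convention on read (and back on write).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .diffexpr import CountMatrix
from .locus import LocusDefinition

__all__ = [
    "read_counts",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_bed_annotation",
    "write_bed_annotation",
    "read_locus",
    "read_config",
    "write_config",
]


def read_counts(path, fmt: str | None = None, feature_type: str = "mRNA") -> CountMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        return read_counts_tsv(path, feature_type)
    if fmt == "mtx":
        return read_counts_mtx(path, feature_type=feature_type)
    raise ValueError(f"unknown counts format {fmt!r}")


def read_counts_tsv(path, feature_type: str = "mRNA") -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = np.argwhere(~np.vectorize(lambda v: str(v).lstrip("-").isdigit())(df.to_numpy(dtype=object)))
        r, c = bad[0]
        raise ValueError(f"non-integer count at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    if np.any(vals != np.round(vals)):
        r, c = np.argwhere(vals != np.round(vals))[0]
        raise ValueError(f"non-integer count at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id: {dup[0]!r}")
    return CountMatrix(vals.astype(np.int64), list(df.index), list(df.columns), feature_type)


def write_counts_tsv(m: CountMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t")


def read_counts_mtx(path, rows_path=None, cols_path=None, feature_type: str = "mRNA") -> CountMatrix:
    """MatrixMarket coordinate counts; implicit zeros become explicit."""
    path = Path(path)
    rows_path = Path(rows_path) if rows_path else path.with_suffix(path.suffix + ".rows")
    cols_path = Path(cols_path) if cols_path else path.with_suffix(path.suffix + ".cols")
    mat = spio.mmread(path)
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if np.any(dense != np.round(dense)):
        raise ValueError("non-integer entries in MatrixMarket counts")
    feature_ids = rows_path.read_text().split()
    sample_ids = cols_path.read_text().split()
    return CountMatrix(dense.astype(np.int64), feature_ids, sample_ids, feature_type)


def write_counts_mtx(m: CountMatrix, path) -> None:
    path = Path(path)
    spio.mmwrite(str(path), sparse.coo_matrix(m.counts))
    # scipy may append .mtx when missing; normalize
    written = path if path.exists() else path.with_suffix(path.suffix + ".mtx")
    if written != path:
        written.rename(path)
    path.with_suffix(path.suffix + ".rows").write_text("\n".join(m.feature_ids) + "\n")
    path.with_suffix(path.suffix + ".cols").write_text("\n".join(m.sample_ids) + "\n")


def read_metadata_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError("metadata must have sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df.set_index("sample_id")["group"]


def write_metadata_tsv(metadata: pd.Series, path) -> None:
    metadata.rename("group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_bed_annotation(path) -> pd.DataFrame:
    """6-column BED -> annotation table in 1-based inclusive coordinates.

    Comment (#), ``track`` and ``browser`` lines are skipped.  A BED feature
    ``start end`` (0-based half-open) becomes ``start+1 .. end``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: BED needs >= 6 columns "
                                 "(chrom, start, end, name, score, strand)")
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            feat_type = parts[6] if len(parts) > 6 else ""
            rows.append((name, chrom, start + 1, end, strand, feat_type))
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end",
                                     "strand", "feature_type"])
    return df.set_index("feature_id")


def write_bed_annotation(annotation: pd.DataFrame, path) -> None:
    """Annotation table (1-based inclusive) -> 6(+1)-column BED."""
    with open(path, "w") as fh:
        for fid, row in annotation.iterrows():
            extra = f"\t{row['feature_type']}" if "feature_type" in annotation.columns else ""
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}"
                     f"\t{fid}\t0\t{row.get('strand', '+')}{extra}\n")


def read_locus(path_or_string) -> LocusDefinition:
    """Locus from a ``chr:start-end`` string, a one-line text file or BED."""
    text = str(path_or_string)
    p = Path(text)
    if ":" in text and "-" in text and not p.exists():
        return LocusDefinition.parse(text)
    if p.suffix == ".bed":
        ann = read_bed_annotation(p)
        row = ann.iloc[0]
        return LocusDefinition(row["chrom"], int(row["start"]), int(row["end"]), str(ann.index[0]))
    return LocusDefinition.parse(p.read_text().strip())


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
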