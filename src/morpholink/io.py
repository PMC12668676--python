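"""File I/O for the formats the pipeline touches: cell feature tables
(CSV/Parquet), 10x-style MatrixMarket expression triplets, expression
normalization, GMT gene sets, and ground-truth export."""
from __future__ import annotations

import gzip
import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import ConfigurationError, METADATA_COLUMNS, REQUIRED_METADATA
from .synthetic import CellFeatureTable, ExpressionTable, SyntheticGroundTruth


# ---------------------------------------------------------------------------
# Cell feature tables
# ---------------------------------------------------------------------------

def split_feature_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split columns into (metadata, feature) lists by the column convention."""
    meta = [c for c in df.columns if c in METADATA_COLUMNS]
    feats = [c for c in df.columns if c not in METADATA_COLUMNS]
    return meta, feats


def read_feature_table(path: str, fields_path: str | None = None) -> CellFeatureTable:
    """Read a cell feature table (CSV or Parquet by extension); metadata and
    feature columns are told apart by the fixed metadata-column convention."""
    if path.endswith(".parquet"):
        cells = pd.read_parquet(path)
        if "cell_id" in cells.columns:
            cells = cells.set_index("cell_id")
    else:
        cells = pd.read_csv(path, index_col=0)
    for col in REQUIRED_METADATA:
        if col not in cells.columns:
            raise ConfigurationError(f"feature table lacks required column {col!r}")
    if "population" not in cells.columns:
        cells["population"] = cells["line"].astype(str) + "_d" + cells["day"].astype(str)
    _, feats = split_feature_columns(cells)
    if fields_path is not None:
        fields = (pd.read_parquet(fields_path) if fields_path.endswith(".parquet")
                  else pd.read_csv(fields_path, index_col=0))
        if "field" in fields.columns:
            fields = fields.set_index("field")
    else:
        fields = pd.DataFrame(index=pd.Index(sorted(cells["field"].unique()), name="field"))
    return CellFeatureTable(cells=cells, fields=fields, feature_cols=feats)


def write_feature_table(table: CellFeatureTable, path: str, fields_path: str | None = None) -> None:
    if path.endswith(".parquet"):
        table.cells.rename_axis("cell_id").reset_index().to_parquet(path, index=False)
    else:
        table.cells.rename_axis("cell_id").to_csv(path)
    if fields_path is not None:
        if fields_path.endswith(".parquet"):
            table.fields.rename_axis("field").reset_index().to_parquet(fields_path, index=False)
        else:
            table.fields.rename_axis("field").to_csv(fields_path)


# ---------------------------------------------------------------------------
# Expression (MatrixMarket triplet, 10x layout: genes x cells)
# ---------------------------------------------------------------------------

def _open_maybe_gz(base: str):
    if os.path.exists(base):
        return open(base, "rb")
    if os.path.exists(base + ".gz"):
        return gzip.open(base + ".gz", "rb")
    raise ConfigurationError(f"missing file {base}(.gz)")


def _read_tsv_column(base: str) -> list[str]:
    with _open_maybe_gz(base) as fh:
        return [line.decode().rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_expression_mtx(directory: str) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read matrix.mtx(.gz) + genes/features.tsv(.gz) + barcodes.tsv(.gz);
    returns (cells x genes sparse matrix, genes, barcodes)."""
    with _open_maybe_gz(os.path.join(directory, "matrix.mtx")) as fh:
        try:
            m = scipy.io.mmread(fh)
        except Exception as exc:
            raise ConfigurationError(f"cannot parse matrix.mtx: {exc}") from exc
    genes_base = os.path.join(directory, "genes.tsv")
    if not (os.path.exists(genes_base) or os.path.exists(genes_base + ".gz")):
        genes_base = os.path.join(directory, "features.tsv")
    genes = _read_tsv_column(genes_base)
    barcodes = _read_tsv_column(os.path.join(directory, "barcodes.tsv"))
    m = sp.csr_matrix(m)
    if m.shape != (len(genes), len(barcodes)):
        raise ConfigurationError(
            f"matrix.mtx is {m.shape} but genes.tsv has {len(genes)} rows and "
            f"barcodes.tsv has {len(barcodes)}"
        )
    return sp.csr_matrix(m.T), genes, barcodes


def write_expression_mtx(matrix, genes: list[str], barcodes: list[str], directory: str) -> None:
    """Write a cells x genes matrix as a 10x-style triplet (genes x cells mtx)."""
    os.makedirs(directory, exist_ok=True)
    m = sp.coo_matrix(np.asarray(matrix)) if not sp.issparse(matrix) else sp.coo_matrix(matrix)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), m.T)
    with open(os.path.join(directory, "genes.tsv"), "w") as fh:
        fh.writelines(f"{g}\t{g}\n" for g in genes)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{b}\n" for b in barcodes)


def normalize_expression(counts, scale_factor: float = 10000.0):
    """Library-size normalize then log-transform: ln(1 + count * sf / total)
    per cell.  Rejects negative counts and zero-total cells (listing them)."""
    dense = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else None
    X = dense if dense is not None else (
        counts.toarray().astype(float) if sp.issparse(counts) else np.asarray(counts, dtype=float)
    )
    if (X < 0).any():
        raise ConfigurationError("negative counts")
    totals = X.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if len(zero):
        ids = (list(counts.index[zero]) if isinstance(counts, pd.DataFrame) else zero.tolist())
        raise ConfigurationError(f"cells with zero total counts: {ids[:10]}")
    out = np.log1p(X * (scale_factor / totals[:, None]))
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


# ---------------------------------------------------------------------------
# GMT gene sets and ground truth
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: dict[str, tuple[str, list[str]]], path: str) -> None:
    """Write gene sets as GMT lines: name <tab> description <tab> genes..."""
    with open(path, "w") as fh:
        for name, (desc, genes) in gene_sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str) -> dict[str, tuple[str, list[str]]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = (parts[1], parts[2:])
    return out


def write_ground_truth(truth: SyntheticGroundTruth, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    truth.W.to_csv(os.path.join(directory, "true_weights.csv"))
    truth.artifact_flags.to_csv(os.path.join(directory, "artifact_flags.csv"))
    payload = {
        "module_blocks": truth.module_blocks,
        "redundant_pairs": truth.redundant_pairs,
        "family_assignment": truth.family_assignment,
    }
    with open(os.path.join(directory, "ground_truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_expression_table(expr: ExpressionTable, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    write_expression_mtx(expr.matrix.to_numpy(), list(expr.matrix.columns),
                         list(expr.matrix.index), directory)
    expr.meta.rename_axis("cell_id").to_csv(os.path.join(directory, "cell_meta.csv"))
    pd.DataFrame({"S": expr.s_score, "G2M": expr.g2m_score}).rename_axis("cell_id").to_csv(
        os.path.join(directory, "cellcycle_scores.csv")
    )
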