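"""Readers and writers for the pipeline's plain-text formats.

Matrices are tab-delimited with a header row and a gene-id first column;
single-cell counts may alternatively arrive as a sparse matrix-exchange
triplet (.mtx) with row/column name files; labels and marker lists are
two-column TSVs; configuration travels as YAML.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio

FLOAT_FORMAT = "%.10g"


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("cell_type").rename_axis("cell_id").to_csv(path, sep="\t")


def read_reference_dense(counts_path, labels_path) -> ad.AnnData:
    """Dense gene x cell TSV + label TSV -> AnnData (cells x genes)."""
    counts = read_matrix(counts_path)
    labels = read_labels(labels_path).reindex(counts.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"cells without labels: {missing}")
    adata = ad.AnnData(
        X=counts.T.to_numpy(dtype=float),
        obs=pd.DataFrame({"cell_type": pd.Categorical(labels)}, index=counts.columns),
        var=pd.DataFrame(index=counts.index),
    )
    adata.var["mito"] = adata.var_names.str.upper().str.startswith("MT-")
    return adata


def read_reference_mtx(mtx_path, genes_path, cells_path, labels_path) -> ad.AnnData:
    """Sparse triplet (genes x cells) + name files + labels -> AnnData."""
    X = spio.mmread(mtx_path).tocsr().T  # cells x genes
    genes = pd.read_csv(genes_path, header=None)[0].astype(str)
    cells = pd.read_csv(cells_path, header=None)[0].astype(str)
    labels = read_labels(labels_path).reindex(cells)
    if labels.isna().any():
        raise ValueError("cells without labels in the label table")
    adata = ad.AnnData(
        X=np.asarray(X.todense(), dtype=float),
        obs=pd.DataFrame({"cell_type": pd.Categorical(labels)}, index=cells),
        var=pd.DataFrame(index=genes),
    )
    adata.var["mito"] = adata.var_names.str.upper().str.startswith("MT-")
    return adata


def write_reference(adata: ad.AnnData, outdir) -> None:
    outdir = Path(outdir)
    counts = pd.DataFrame(
        np.asarray(adata.X).T, index=adata.var_names, columns=adata.obs_names
    )
    write_matrix(counts, outdir / "reference_counts.tsv")
    write_labels(adata.obs["cell_type"].astype(str), outdir / "reference_labels.tsv")


def write_signature(basis: pd.DataFrame, path) -> None:
    """Conventional deconvolution text format: gene symbol first, linear scale."""
    basis.rename_axis("GeneSymbol").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_signature(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_marker_sets(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {ct: set(grp.iloc[:, 1]) for ct, grp in df.groupby(df.columns[0])}


def write_marker_sets(markers: dict, path) -> None:
    rows = [
        {"cell_type": ct, "gene": g} for ct in sorted(markers) for g in sorted(markers[ct])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _plain(obj):
    if is_dataclass(obj):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=True)


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
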