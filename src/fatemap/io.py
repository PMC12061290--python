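"""Matrix and table I/O: MTX + gene/barcode TSVs, dense TSV toys, metadata."""

from __future__ import annotations

import gzip
import io
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def open_text_writer(path: str | Path):
    """Text writer; .gz paths get deterministic gzip (no name/mtime in header)."""
    path = str(path)
    if path.endswith(".gz"):
        gz = gzip.GzipFile(
            filename="", mode="wb", fileobj=open(path, "wb"),
            compresslevel=1, mtime=0,
        )
        return io.TextIOWrapper(gz)
    return open(path, "wt")


def read_matrix_dir(path: str | Path) -> ad.AnnData:
    """Read an MTX triplet directory (matrix.mtx, genes.tsv, barcodes.tsv).

    The MTX is genes x cells (the common convention); the returned AnnData
    is cells x genes.
    """
    path = Path(path)
    mtx = scipy.io.mmread(path / "matrix.mtx")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    X = sp.csr_matrix(mtx.T)
    adata = ad.AnnData(X=X)
    adata.var_names = list(genes)
    adata.obs_names = list(barcodes)
    return adata


def write_matrix_dir(adata: ad.AnnData, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(X.T))
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_dense_tsv(path: str | Path) -> ad.AnnData:
    """Dense cells x genes TSV with a barcode index column (toy inputs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    adata = ad.AnnData(X=df.to_numpy(dtype=float))
    adata.obs_names = list(df.index.astype(str))
    adata.var_names = list(df.columns.astype(str))
    return adata


def attach_metadata(adata: ad.AnnData, path: str | Path, key: str = "barcode") -> ad.AnnData:
    """Left-join a barcode-keyed metadata TSV onto ``adata.obs``."""
    meta = pd.read_csv(path, sep="\t").set_index(key)
    missing = set(adata.obs_names) - set(meta.index)
    if missing:
        raise ValueError(f"{len(missing)} matrix barcodes missing from metadata")
    adata.obs = adata.obs.join(meta.loc[adata.obs_names], how="left")
    return adata
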