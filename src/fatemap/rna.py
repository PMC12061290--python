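"""scRNA count-matrix QC, normalization, HVG selection, and expression scores.

Cells with fewer than 500 transcripts, or with more than 20% of transcripts
from mitochondria-encoded genes, are removed.  Normalization is
ln(CPM/100 + 1) per cell; highly variable genes are ranked by mean-binned,
z-scored dispersion; gene-set scores follow the mean-minus-binned-control
construction; the gene-pair co-expression score multiplies two cell-type
mean normalized profiles per gene.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

RP_PREFIXES = ("Rps", "Rpl")  # ribosomal-protein gene identifiers (mouse casing)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def qc_filter_cells(
    adata: ad.AnnData,
    min_transcripts: int = 500,
    max_mito_frac: float = 0.20,
    mito_prefix: str = "mt-",
) -> ad.AnnData:
    """Keep cells with >= ``min_transcripts`` total counts and mito fraction
    <= ``max_mito_frac``.

    Mitochondrial genes are identified by a case-sensitive identifier prefix
    (annotation-dependent).  When no gene matches, the mito filter is skipped
    with a warning.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = totals >= min_transcripts
    mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    if mito.any():
        mito_counts = np.asarray(adata[:, mito].X.sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        keep &= frac <= max_mito_frac
    else:
        warnings.warn(
            f"no genes match mito prefix {mito_prefix!r}; mito filter skipped",
            UserWarning,
            stacklevel=2,
        )
    return adata[keep].copy()


def normalize_ln_cpm100(adata: ad.AnnData, layer: str = "normalized") -> ad.AnnData:
    """ln(CPM/100 + 1) per cell, stored as ``adata.layers['normalized']``.

    CPM/100 equals counts per 10,000, so a cell expressing a single gene
    maps that gene to ln(10001).
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError(
            "cells with zero total counts present; run qc_filter_cells first"
        )
    X = _dense(adata.X).astype(float)
    norm = np.log1p(X / totals[:, None] * 1e4)
    adata.layers[layer] = norm
    return adata


def select_hvg(adata: ad.AnnData, n: int = 2000, n_bins: int = 20,
               layer: str = "normalized") -> list[str]:
    """Top-``n`` highly variable genes by mean-binned, z-scored dispersion.

    Genes are binned by mean normalized expression (equal-frequency bins),
    dispersion = variance/mean is z-scored within each bin, and the top ``n``
    are returned with a deterministic tie-break on gene identifier.
    """
    X = np.asarray(adata.layers[layer]) if layer in adata.layers else _dense(adata.X)
    means = X.mean(axis=0)
    variances = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, variances / means, np.nan)
    df = pd.DataFrame(
        {"gene": list(adata.var_names), "mean": means, "dispersion": dispersion}
    ).dropna(subset=["dispersion"])
    df = df[df["dispersion"] > 0]
    if len(df) == 0:
        raise ValueError("no gene has nonzero variance")
    df["bin"] = pd.qcut(df["mean"], q=min(n_bins, len(df)), duplicates="drop")
    z = df.groupby("bin", observed=True)["dispersion"].transform(
        lambda d: (d - d.mean()) / d.std(ddof=1) if len(d) > 1 and d.std(ddof=1) > 0 else d * 0.0
    )
    df["z"] = z
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    if len(df) < n:
        warnings.warn(
            f"only {len(df)} qualifying genes for n={n}; returning all",
            UserWarning,
            stacklevel=2,
        )
        return list(df["gene"])
    return list(df["gene"].iloc[:n])


def score_gene_set(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    layer: str = "normalized",
    name: str = "score",
) -> pd.Series:
    """Mean-minus-binned-control gene-set score per cell.

    Genes are binned by mean expression into ``n_bins`` equal-frequency bins;
    for each set gene, ``n_ctrl`` control genes are drawn (seeded, without
    replacement where possible) from the same bin; score = mean over set
    genes - mean over the pooled controls.
    """
    present = [g for g in gene_set if g in set(adata.var_names)]
    if not present:
        raise ValueError(f"no gene of the set present in the matrix: {sorted(gene_set)[:10]}")
    X = np.asarray(adata.layers[layer]) if layer in adata.layers else _dense(adata.X)
    genes = pd.Index(adata.var_names)
    means = pd.Series(X.mean(axis=0), index=genes)
    bins = pd.qcut(means.rank(method="first"), q=min(n_bins, len(means)), labels=False,
                   duplicates="drop")
    rng = np.random.default_rng(seed)
    ctrl: list[str] = []
    present_set = set(present)
    for g in present:
        pool = means.index[(bins == bins[g]) & ~means.index.isin(present_set)]
        if len(pool) == 0:
            continue
        k = min(n_ctrl, len(pool))
        ctrl.extend(rng.choice(pool, size=k, replace=False))
    set_idx = genes.get_indexer(present)
    score = X[:, set_idx].mean(axis=1)
    if ctrl:
        ctrl_idx = genes.get_indexer(pd.Index(ctrl))
        score = score - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=name)


def score_rp(adata: ad.AnnData, seed: int = 0, **kwargs) -> pd.Series:
    """Ribosomal-protein score: score_gene_set over Rps*/Rpl* genes."""
    rp = [g for g in adata.var_names if g.startswith(RP_PREFIXES)]
    if not rp:
        raise ValueError("no ribosomal-protein (Rps*/Rpl*) genes in the matrix")
    return score_gene_set(adata, rp, seed=seed, name="rp_score", **kwargs)


def pair_coexpression_score(profile_a: pd.Series, profile_b: pd.Series) -> pd.Series:
    """Per-gene product of two cell-type mean normalized profiles, ranked descending.

    High scores mark genes highly expressed in both members of a matched
    cell-type pair.
    """
    shared = profile_a.index.intersection(profile_b.index)
    if len(shared) == 0:
        raise ValueError("profiles share no genes")
    score = (profile_a.loc[shared] * profile_b.loc[shared]).sort_values(
        ascending=False, kind="mergesort"
    )
    score.name = "pair_score"
    return score
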