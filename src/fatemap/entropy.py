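"""CCAT single-cell potency: transcriptome-connectome correlation.

CCAT approximates network (signaling) entropy as the Pearson correlation
between a cell's expression vector and the degree vector of a
protein-protein-interaction connectome, over their shared genes.  Cross-
species matrices are first projected into the connectome's (human) gene
space through a homology weight matrix: the binary homology incidence
(one-to-one, one-to-many, many-to-one, many-to-many) normalized so each
human gene's incoming weights sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class Connectome:
    """Gene degrees of an undirected PPI network; isolated genes excluded."""

    degrees: pd.Series  # index gene, value integer degree >= 1

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame | str | Path) -> "Connectome":
        if isinstance(edges, (str, Path)):
            edges = pd.read_csv(edges, sep="\t", header=None, names=["a", "b"])
        else:
            edges = edges.iloc[:, :2].set_axis(["a", "b"], axis=1)
        edges = edges[edges["a"] != edges["b"]]  # self-loops carry no signal here
        incidence = pd.concat([edges["a"], edges["b"]]).value_counts()
        return cls(degrees=incidence.sort_index().astype(int))


@dataclass
class HomologyWeights:
    """W: source-species genes x human genes; each human-gene column sums to 1."""

    matrix: pd.DataFrame  # rows source genes, columns human genes

    def __post_init__(self) -> None:
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums[colsums > 0], 1.0):
            raise ValueError("human-gene columns must sum to 1")

    @classmethod
    def identity(cls, genes: list[str]) -> "HomologyWeights":
        return cls(matrix=pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes))


def build_homology_weights(pairs: pd.DataFrame | str | Path) -> HomologyWeights:
    """Binary homology incidence column-normalized per human gene.

    ``pairs`` is a two-column (source_gene, human_gene) table; duplicate
    identical pairs are collapsed with a warning.  A source gene homologous
    to several human genes contributes to each human-gene column, and the
    column of a human gene with k homologs carries weight 1/k per homolog.
    """
    if isinstance(pairs, (str, Path)):
        pairs = pd.read_csv(pairs, sep="\t", header=None, names=["source", "human"])
    else:
        pairs = pairs.iloc[:, :2].set_axis(["source", "human"], axis=1)
    if len(pairs) == 0:
        raise ValueError("empty homology table")
    pairs = pairs.astype(str)
    if (pairs["source"].str.strip() == "").any() or (pairs["human"].str.strip() == "").any():
        raise ValueError("blank gene identifiers in homology table")
    deduped = pairs.drop_duplicates()
    if len(deduped) < len(pairs):
        warnings.warn(
            f"{len(pairs) - len(deduped)} duplicate homology pairs collapsed",
            UserWarning,
            stacklevel=2,
        )
    incidence = pd.crosstab(deduped["source"], deduped["human"]).clip(upper=1).astype(float)
    return HomologyWeights(matrix=incidence / incidence.sum(axis=0))


def project_expression(
    adata: ad.AnnData, weights: HomologyWeights, layer: str = "normalized"
) -> tuple[pd.DataFrame, int]:
    """Project a cells x source-genes matrix into human gene space through W.

    Returns (cells x human-genes DataFrame, number of matrix genes dropped
    because they are absent from W's source rows).
    """
    X = adata.layers[layer] if layer in adata.layers else adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    genes = pd.Index(adata.var_names)
    shared = genes.intersection(weights.matrix.index)
    dropped = len(genes) - len(shared)
    if len(shared) == 0:
        raise ValueError("no matrix gene appears in the homology weight rows")
    W = weights.matrix.loc[shared]
    projected = X[:, genes.get_indexer(shared)] @ W.to_numpy()
    return pd.DataFrame(projected, index=adata.obs_names, columns=W.columns), dropped


def ccat(
    expression: pd.DataFrame,
    connectome: Connectome,
    log_degrees: bool = False,
    min_shared: int = 10,
) -> pd.Series:
    """Per-cell Pearson correlation of expression with connectome degree.

    Degrees are used raw by default (``log_degrees`` switches to
    log-transformed degrees).  Zero-variance cells over the shared genes
    score NaN (flagged undefined).  The score is invariant to per-cell
    positive affine transforms of expression and to gene order.
    """
    shared = expression.columns.intersection(connectome.degrees.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with the connectome (need >= {min_shared})"
        )
    X = expression[shared].to_numpy(dtype=float)
    d = connectome.degrees.loc[shared].to_numpy(dtype=float)
    if log_degrees:
        d = np.log(d)
    d = d - d.mean()
    d_norm = np.sqrt((d**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (Xc @ d) / (x_norm * d_norm)
    scores[x_norm == 0] = np.nan
    return pd.Series(scores, index=expression.index, name="ccat")
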