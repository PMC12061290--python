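"""Cross-dataset cell-type matching: pseudo-cells and neighbor-voting AUROC.

Shallow-coverage datasets are stabilized by summing counts over disjoint
groups of 100 cells from one cluster ("pseudo-cells").  Replicability of a
cell-type pair across two datasets is the mean AUROC of a neighbor-voting
scheme on the cross-dataset Spearman correlation network; pairs with
AUROC > 0.9 (strict) count as strongly consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class PseudoCellMatrix:
    """Summed count profiles with provenance (source cluster, member count)."""

    counts: pd.DataFrame  # pseudo-cells x genes
    provenance: pd.DataFrame  # index pseudo-cell; columns cluster, n_members
    seed: int
    dropped_cells: int


def make_pseudocells(
    counts: pd.DataFrame,
    cluster_labels: pd.Series,
    size: int = 100,
    seed: int = 0,
    absorb_remainder: bool = False,
) -> PseudoCellMatrix:
    """Aggregate counts from disjoint, seeded groups of ``size`` cells per cluster.

    Cells are shuffled with the seed and partitioned into groups of exactly
    ``size``; the remainder (< size) is dropped unless ``absorb_remainder``
    pools it into the last group.  Clusters smaller than ``size`` are skipped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    labels = cluster_labels.loc[counts.index]
    rows, prov, dropped = [], [], 0
    for cluster in sorted(labels.unique()):
        members = np.array(labels.index[labels == cluster])
        if len(members) < size:
            warnings.warn(
                f"cluster {cluster!r} has {len(members)} < {size} cells; skipped",
                UserWarning,
                stacklevel=2,
            )
            dropped += len(members)
            continue
        members = members[rng.permutation(len(members))]
        n_groups = len(members) // size
        remainder = len(members) - n_groups * size
        for k in range(n_groups):
            group = members[k * size : (k + 1) * size]
            if absorb_remainder and k == n_groups - 1 and remainder:
                group = np.concatenate([group, members[n_groups * size :]])
                remainder = 0
            rows.append(counts.loc[group].sum(axis=0).rename(f"{cluster}.pc{k}"))
            prov.append({"pseudocell": f"{cluster}.pc{k}", "cluster": cluster,
                         "n_members": len(group)})
        dropped += remainder
    if not rows:
        raise ValueError("no cluster reached the pseudo-cell size; nothing aggregated")
    return PseudoCellMatrix(
        counts=pd.DataFrame(rows),
        provenance=pd.DataFrame(prov).set_index("pseudocell"),
        seed=seed,
        dropped_cells=dropped,
    )


def _auroc(pos_votes: np.ndarray, neg_votes: np.ndarray) -> float:
    """Mann-Whitney rank AUROC with average ranks on ties."""
    ranks = rankdata(np.concatenate([pos_votes, neg_votes]))
    n_pos, n_neg = len(pos_votes), len(neg_votes)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def neighbor_voting_auroc(
    profiles_a: pd.DataFrame,
    labels_a: pd.Series,
    profiles_b: pd.DataFrame,
    labels_b: pd.Series,
    hvg: list[str] | None = None,
) -> pd.DataFrame:
    """Cell-type x cell-type mean AUROC matrix by cross-dataset neighbor voting.

    Over the shared (optionally HVG-restricted) genes, each B sample's
    Spearman correlations to the A samples are rank-standardized to [0, 1];
    the vote of B sample b for A type t is the mean standardized correlation
    of b to the A samples of type t; the (t, s) entry is the AUROC of those
    votes for discriminating B samples of type s from the rest.  Types with
    fewer than two samples are excluded with a warning.  Rank-based
    throughout, hence invariant to monotone transforms of expression.
    """
    shared = profiles_a.columns.intersection(profiles_b.columns)
    if hvg is not None:
        shared = shared.intersection(pd.Index(hvg))
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (need >= 10)")

    def usable(labels: pd.Series, which: str) -> list:
        counts = labels.value_counts()
        small = counts[counts < 2]
        if len(small):
            warnings.warn(
                f"dataset {which}: types with <2 samples excluded: {list(small.index)}",
                UserWarning,
                stacklevel=3,
            )
        return sorted(counts[counts >= 2].index)

    types_a = usable(labels_a.loc[profiles_a.index], "A")
    types_b = usable(labels_b.loc[profiles_b.index], "B")
    if len(types_a) < 2 or len(types_b) < 2:
        raise ValueError("need >= 2 usable cell types per dataset")

    A = profiles_a.loc[labels_a.index[labels_a.isin(types_a)], shared]
    B = profiles_b.loc[labels_b.index[labels_b.isin(types_b)], shared]
    la, lb = labels_a.loc[A.index], labels_b.loc[B.index]

    # Spearman: Pearson on within-sample gene ranks.
    ra = np.apply_along_axis(rankdata, 1, A.to_numpy(dtype=float))
    rb = np.apply_along_axis(rankdata, 1, B.to_numpy(dtype=float))
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    # constant profiles (all ranks tied) get zero correlation to everything
    ra /= np.where(
        np.linalg.norm(ra, axis=1, keepdims=True) == 0, 1.0,
        np.linalg.norm(ra, axis=1, keepdims=True),
    )
    rb /= np.where(
        np.linalg.norm(rb, axis=1, keepdims=True) == 0, 1.0,
        np.linalg.norm(rb, axis=1, keepdims=True),
    )
    corr = rb @ ra.T  # B samples x A samples

    # rank-standardize each B sample's correlation profile to [0, 1]
    std = np.apply_along_axis(rankdata, 1, corr)
    std = (std - 1) / (std.shape[1] - 1) if std.shape[1] > 1 else std * 0 + 0.5

    out = pd.DataFrame(index=types_a, columns=types_b, dtype=float)
    la_arr, lb_arr = la.to_numpy(), lb.to_numpy()
    for t in types_a:
        votes = std[:, la_arr == t].mean(axis=1)
        for s in types_b:
            pos = votes[lb_arr == s]
            neg = votes[lb_arr != s]
            out.loc[t, s] = _auroc(pos, neg)
    out.index.name, out.columns.name = "type_a", "type_b"
    return out


def match_cell_types(auroc: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """All (type_a, type_b) pairs with AUROC strictly > threshold, sorted descending."""
    auroc = auroc.rename_axis(index="type_a", columns="type_b")
    pairs = auroc.stack().rename("auroc").reset_index()
    matched = pairs[pairs["auroc"] > threshold]
    return matched.sort_values("auroc", ascending=False, kind="mergesort", ignore_index=True)
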