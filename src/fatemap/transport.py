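"""Time-course fate mapping by unbalanced entropic optimal transport.

Couplings between adjacent timepoints minimize

    <C, pi> + epsilon * KL(pi || a (x) b)
            + lambda1 * KL(pi 1 || a) + lambda2 * KL(pi^T 1 || b)

where ``a`` is the growth-weighted source distribution, ``b`` the uniform
target distribution, and ``C`` the squared Euclidean cost normalized by its
median.  The solver is log-domain stabilized Sinkhorn scaling with the
unbalanced exponent lambda/(lambda+epsilon).  Defaults follow the study's
time-course setting: lambda1=1, lambda2=50, epsilon=0.05, growth_iters=1
(no growth re-estimation loop).

Long-range couplings compose row-normalized adjacent couplings as a Markov
chain; ancestor distributions pull a target cell set backward through the
chain; trajectory divergence is half the total variation distance between
two ancestor distributions; membership applies the strict 0.00025
probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class OTParams:
    lambda1: float = 1.0    # source-marginal KL penalty
    lambda2: float = 50.0   # target-marginal KL penalty (near-balanced target)
    epsilon: float = 0.05   # entropic regularization
    growth_iters: int = 1
    max_sinkhorn_iters: int = 5000
    tol: float = 1e-8       # convergence on dual change

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.epsilon) <= 0:
            raise ValueError("lambda1, lambda2, epsilon must be > 0")
        if self.growth_iters < 1:
            raise ValueError("growth_iters must be >= 1")


@dataclass
class Coupling:
    """One between-timepoint transport map with convergence diagnostics.

    ``matrix`` is the minimizer rescaled to total mass 1 (a joint
    distribution over source x target cells; every downstream query —
    pull-back, Markov composition — is invariant to this rescaling).
    ``raw_mass`` is the unrescaled minimizer's total mass, which the
    unbalanced source penalty lets drift slightly below 1.
    """

    matrix: pd.DataFrame  # rows source cells, columns target cells
    converged: bool
    n_iters: int
    raw_mass: float = 1.0

    @property
    def total_mass(self) -> float:
        return float(self.matrix.to_numpy().sum())


def squared_euclidean_cost(X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Squared Euclidean pairwise cost, normalized by its median."""
    C = cdist(X0, X1, metric="sqeuclidean")
    med = np.median(C)
    return C / med if med > 0 else C


def transport_map(
    X0: np.ndarray,
    X1: np.ndarray,
    growth: np.ndarray | None = None,
    params: OTParams = OTParams(),
    source_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> Coupling:
    """Unbalanced entropic coupling between two embedded cell populations.

    ``growth`` (per source cell, > 0) weights the source marginal; the
    default 1.0 everywhere makes it uniform.  Non-convergence at
    ``max_sinkhorn_iters`` returns the current iterate with
    ``converged=False``.
    """
    X0, X1 = np.asarray(X0, dtype=float), np.asarray(X1, dtype=float)
    if X0.shape[1] != X1.shape[1]:
        raise ValueError("embeddings must share dimensionality")
    n, m = len(X0), len(X1)
    if growth is None:
        growth = np.ones(n)
    growth = np.asarray(growth, dtype=float)
    if np.any(growth <= 0):
        raise ValueError("growth estimates must be > 0")

    a = growth / growth.sum()
    b = np.full(m, 1.0 / m)
    eps = params.epsilon
    alpha1 = params.lambda1 / (params.lambda1 + eps)
    alpha2 = params.lambda2 / (params.lambda2 + eps)

    C = squared_euclidean_cost(X0, X1)
    log_k = np.log(a)[:, None] + np.log(b)[None, :] - C / eps
    lu = np.zeros(n)
    lv = np.zeros(m)
    converged = False
    it = 0
    for it in range(1, params.max_sinkhorn_iters + 1):
        lu_prev, lv_prev = lu, lv
        lu = alpha1 * (np.log(a) - logsumexp(log_k + lv[None, :], axis=1))
        lv = alpha2 * (np.log(b) - logsumexp(log_k + lu[:, None], axis=0))
        dual_change = eps * max(
            np.abs(lu - lu_prev).max(), np.abs(lv - lv_prev).max()
        )
        if dual_change < params.tol:
            converged = True
            break
    pi = np.exp(lu[:, None] + log_k + lv[None, :])
    raw_mass = float(pi.sum())
    pi = pi / raw_mass
    matrix = pd.DataFrame(
        pi,
        index=source_ids if source_ids is not None else range(n),
        columns=target_ids if target_ids is not None else range(m),
    )
    return Coupling(matrix=matrix, converged=converged, n_iters=it, raw_mass=raw_mass)


def ordered_timepoints(series: pd.Series) -> list:
    """Chronological order of a timepoint column.

    Ordered categoricals keep their declared order; otherwise labels sort by
    any embedded number ("D6" before "D12"), falling back to plain sort.
    """
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [t for t in series.cat.categories if t in set(series)]
    uniq = list(pd.unique(series))
    import re

    def key(label):
        m = re.search(r"\d+(\.\d+)?", str(label))
        return (float(m.group()), str(label)) if m else (float("inf"), str(label))

    try:
        return sorted(uniq, key=float)
    except (TypeError, ValueError):
        return sorted(uniq, key=key)


@dataclass
class TransportChain:
    """Ordered timepoints with adjacent couplings; supports pull-back queries."""

    timepoints: list
    couplings: dict = field(default_factory=dict)  # (t_k, t_{k+1}) -> Coupling
    cell_ids: dict = field(default_factory=dict)   # timepoint -> list of cell ids

    def add(self, t0, t1, coupling: Coupling) -> None:
        if self.timepoints.index(t1) != self.timepoints.index(t0) + 1:
            raise ValueError(f"({t0}, {t1}) are not adjacent timepoints")
        self.couplings[(t0, t1)] = coupling
        self.cell_ids.setdefault(t0, list(coupling.matrix.index))
        self.cell_ids.setdefault(t1, list(coupling.matrix.columns))

    def markov(self, t0, t1) -> pd.DataFrame:
        """Row-normalized adjacent coupling (forward transition matrix)."""
        m = self.couplings[(t0, t1)].matrix
        return m.div(m.sum(axis=1), axis=0)


def fit_chain(
    adata: ad.AnnData,
    timepoint_col: str = "timepoint",
    params: OTParams = OTParams(),
    n_pcs: int = 30,
    layer: str = "normalized",
    hvg: list[str] | None = None,
    growth: pd.Series | None = None,
    seed: int = 0,
) -> TransportChain:
    """Fit couplings between every adjacent timepoint pair.

    The cost embedding is the top ``n_pcs`` principal components of the
    ln-normalized matrix (over ``hvg`` when given), computed jointly across
    all timepoints so adjacent clouds share one space.
    """
    X = np.asarray(adata.layers[layer]) if layer in adata.layers else np.asarray(adata.X)
    if hvg is not None:
        idx = pd.Index(adata.var_names).get_indexer(hvg)
        X = X[:, idx[idx >= 0]]
    n_comp = min(n_pcs, X.shape[1], X.shape[0] - 1)
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(X)

    tps = ordered_timepoints(adata.obs[timepoint_col])
    chain = TransportChain(timepoints=tps)
    for t0, t1 in zip(tps[:-1], tps[1:]):
        m0 = (adata.obs[timepoint_col] == t0).to_numpy()
        m1 = (adata.obs[timepoint_col] == t1).to_numpy()
        g = None
        if growth is not None:
            g = growth.loc[adata.obs_names[m0]].to_numpy()
        chain.add(
            t0,
            t1,
            transport_map(
                emb[m0],
                emb[m1],
                growth=g,
                params=params,
                source_ids=list(adata.obs_names[m0]),
                target_ids=list(adata.obs_names[m1]),
            ),
        )
    return chain


def compose_chain(chain: TransportChain, t_a, t_b) -> pd.DataFrame:
    """Long-range coupling from t_a to t_b: Markov product of the factors,
    rescaled to total mass 1."""
    tps = chain.timepoints
    ia, ib = tps.index(t_a), tps.index(t_b)
    if ia >= ib:
        raise ValueError("t_a must precede t_b")
    for t0, t1 in zip(tps[ia:ib], tps[ia + 1 : ib + 1]):
        if (t0, t1) not in chain.couplings:
            raise ValueError(f"missing coupling for ({t0}, {t1})")
    out = chain.markov(tps[ia], tps[ia + 1])
    for t0, t1 in zip(tps[ia + 1 : ib], tps[ia + 2 : ib + 1]):
        out = out @ chain.markov(t0, t1)
    return out / out.to_numpy().sum()


@dataclass
class AncestorDistribution:
    """Normalized probability over the cells of one earlier timepoint."""

    timepoint: object
    probabilities: pd.Series
    target_name: str = ""

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("ancestor distribution must be normalized and >= 0")


def pull_back(
    target_cells: list[str], chain: TransportChain, t_k, target_name: str = ""
) -> dict:
    """Ancestor distributions of a target cell set at every earlier timepoint.

    The indicator over the target cells is normalized and propagated
    backward through the row-normalized couplings; each returned vector
    sums to one.
    """
    if not target_cells:
        raise ValueError("target set is empty")
    ids_k = chain.cell_ids[t_k]
    missing = sorted(set(target_cells) - set(ids_k))
    if missing:
        raise ValueError(f"target cells absent from {t_k}: {missing[:10]}")
    p = pd.Series(0.0, index=ids_k)
    p.loc[list(target_cells)] = 1.0 / len(target_cells)

    out: dict = {}
    tps = chain.timepoints
    ik = tps.index(t_k)
    for j in range(ik - 1, -1, -1):
        t0, t1 = tps[j], tps[j + 1]
        m = chain.markov(t0, t1)
        p = m @ p
        p = p / p.sum()
        out[t0] = AncestorDistribution(
            timepoint=t0, probabilities=p.copy(), target_name=target_name
        )
    return out


def membership(dist: AncestorDistribution, threshold: float = 0.00025) -> list[str]:
    """Cells with ancestor probability strictly greater than the threshold."""
    p = dist.probabilities
    return sorted(p.index[p > threshold])


def ancestor_divergence(p: pd.Series | AncestorDistribution,
                        q: pd.Series | AncestorDistribution) -> float:
    """Half the total variation distance: 0.5 * sum |p_i - q_i|, in [0, 1]."""
    if isinstance(p, AncestorDistribution):
        p = p.probabilities
    if isinstance(q, AncestorDistribution):
        q = q.probabilities
    if not p.index.equals(q.index):
        raise ValueError("ancestor distributions are over different cell indices")
    return float(0.5 * np.abs(p.to_numpy() - q.to_numpy()).sum())


def gene_trend(
    adata: ad.AnnData,
    distributions: dict,
    genes: list[str] | None = None,
    layer: str = "normalized",
) -> pd.DataFrame:
    """Distribution-weighted mean expression per gene per timepoint.

    ``distributions`` maps timepoint -> AncestorDistribution (or Series over
    that timepoint's cells); the trend at t is sum_i dist_t(i) * x(i, gene).
    """
    X = np.asarray(adata.layers[layer]) if layer in adata.layers else np.asarray(adata.X)
    var = pd.Index(adata.var_names)
    cols = var if genes is None else pd.Index(genes)
    gidx = var.get_indexer(cols)
    if np.any(gidx < 0):
        raise ValueError(f"genes absent from matrix: {list(cols[gidx < 0])[:10]}")
    obs = pd.Index(adata.obs_names)
    rows = {}
    for t, dist in distributions.items():
        p = dist.probabilities if isinstance(dist, AncestorDistribution) else dist
        cidx = obs.get_indexer(p.index)
        rows[t] = p.to_numpy() @ X[np.ix_(cidx, gidx)]
    trend = pd.DataFrame(rows, index=cols).T.sort_index()
    trend.index.name = "timepoint"
    return trend


def driver_correlation(
    adata: ad.AnnData, fate_probabilities: pd.Series, layer: str = "normalized"
) -> pd.Series:
    """Per-gene Pearson correlation with a fate-probability vector, ranked.

    Putative lineage drivers rank first.  Zero-variance genes score NaN and
    sort last; a constant fate vector is an error.
    """
    p = fate_probabilities.loc[adata.obs_names].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("fate probabilities must lie in [0, 1]")
    if len(p) < 20:
        raise ValueError("need at least 20 cells")
    if np.std(p) == 0:
        raise ValueError("fate-probability vector is constant")
    X = np.asarray(adata.layers[layer]) if layer in adata.layers else np.asarray(adata.X)
    pc = p - p.mean()
    Xc = X - X.mean(axis=0)
    x_norm = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (pc @ Xc) / (x_norm * np.linalg.norm(pc))
    corr[x_norm == 0] = np.nan
    s = pd.Series(corr, index=adata.var_names, name="driver_correlation")
    return s.sort_values(ascending=False, na_position="last", kind="mergesort")
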