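"""Spatial cross-correlation of cell-type proportions on hex lattices.

Builds first-order adjacency with a distance filter capped at six neighbors
per spot, expands neighborhoods to a physical radius via graph distance,
computes the bivariate-Moran spatial cross-correlation over all unordered
cell-type pairs (including self-pairs), assesses significance with a
spot-label permutation null, adjusts within sample by Benjamini-Hochberg,
pools across samples with Fisher's method, and clusters the pooled matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from tissuestates._errors import InvalidArgumentError, UndefinedStatisticError
from tissuestates.signatures import bh_adjust
from tissuestates.synthetic import SpatialDataset


@dataclass
class AdjacencyGraph:
    """Symmetric binary spot-adjacency weights."""

    weights: sparse.csr_matrix
    spot_ids: np.ndarray
    order: int = 1
    filter_dist: float | None = None

    def __post_init__(self):
        w = self.weights
        if (w != w.T).nnz != 0:
            raise InvalidArgumentError("weights must be symmetric")
        if w.diagonal().any():
            raise InvalidArgumentError("weights must have zero diagonal")

    @property
    def W(self) -> float:
        """Sum of all weights."""
        return float(self.weights.sum())

    @property
    def max_degree(self) -> int:
        return int(np.asarray(self.weights.sum(axis=1)).max())


@dataclass
class CrossCorrelationResult:
    """SCC matrix with permutation p-values and pooled significance."""

    scc: pd.DataFrame
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None
    pooled_p: pd.DataFrame | None = None
    significant: pd.DataFrame | None = None
    sample_id: str | None = None

    @property
    def n_pairs(self) -> int:
        t = self.scc.shape[0]
        return t * (t + 1) // 2


# ---------------------------------------------------------------------------


def hex_adjacency(ds: SpatialDataset, pitch_um: float = 100.0) -> AdjacencyGraph:
    """First-order adjacency from a distance filter capped at 6 neighbors.

    The cutoff is searched downward from 1.2x pitch in 0.1-pitch steps until
    no spot has more than six neighbors within it.
    """
    if ds.n_spots < 2:
        raise InvalidArgumentError("need at least 2 spots")
    xy = ds.positions[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(np.unique(xy, axis=0)) != len(xy):
        raise InvalidArgumentError("duplicate spot coordinates")
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    for mult in range(12, 0, -1):
        cutoff = mult * 0.1 * pitch_um
        adj = d <= cutoff
        if adj.sum(axis=1).max() <= 6:
            w = sparse.csr_matrix(adj.astype(np.int8))
            return AdjacencyGraph(
                weights=w,
                spot_ids=ds.positions.index.to_numpy(),
                order=1,
                filter_dist=cutoff,
            )
    raise InvalidArgumentError(
        "no distance filter down to 0.1 pitch keeps every spot at <= 6 neighbors"
    )


def expand_neighborhood(
    g: AdjacencyGraph, radius_um: float, pitch_um: float
) -> AdjacencyGraph:
    """Connect every spot to all spots within ``round(radius/pitch)`` hops."""
    if g.order != 1:
        raise InvalidArgumentError("expand_neighborhood expects an order-1 graph")
    k = int(round(radius_um / pitch_um))
    if radius_um < pitch_um or k <= 1:
        if radius_um < pitch_um:
            warnings.warn(
                "radius below pitch; returning the order-1 graph unchanged",
                stacklevel=2,
            )
        return AdjacencyGraph(
            weights=g.weights.copy(),
            spot_ids=g.spot_ids.copy(),
            order=1,
            filter_dist=g.filter_dist,
        )
    dist = shortest_path(g.weights, method="D", unweighted=True, directed=False)
    adj = (dist >= 1) & (dist <= k)
    return AdjacencyGraph(
        weights=sparse.csr_matrix(adj.astype(np.int8)),
        spot_ids=g.spot_ids.copy(),
        order=k,
        filter_dist=g.filter_dist,
    )


def spatial_cross_correlation(
    x: np.ndarray, y: np.ndarray, g: AdjacencyGraph
) -> float:
    """Bivariate Moran spatial cross-correlation of two spot variables.

    ``SCC = (N / W) * sum_ij w_ij (x_i - xbar)(y_j - ybar) /
    sqrt(sum_i (x_i - xbar)^2 * sum_j (y_j - ybar)^2)``; symmetric in (x, y)
    because the weights are symmetric.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.weights.shape[0]
    if len(x) != n or len(y) != n:
        raise InvalidArgumentError("variable length must match spot count")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = (xc**2).sum(), (yc**2).sum()
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("constant variable: SCC undefined")
    num = float(xc @ (g.weights @ yc))
    return (n / g.W) * num / np.sqrt(sx * sy)


def _scc_matrix_from_values(
    vals: np.ndarray, g: AdjacencyGraph
) -> np.ndarray:
    """SCC over all column pairs of ``vals``; constant columns give NaN."""
    n = vals.shape[0]
    centered = vals - vals.mean(axis=0, keepdims=True)
    ss = (centered**2).sum(axis=0)
    num = centered.T @ (g.weights @ centered)
    num = (num + num.T) / 2.0  # enforce exact symmetry
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(divide="ignore", invalid="ignore"):
        scc = (n / g.W) * num / denom
    scc[:, ss == 0] = np.nan
    scc[ss == 0, :] = np.nan
    return scc


def scc_matrix(ds: SpatialDataset, g: AdjacencyGraph) -> CrossCorrelationResult:
    """Spatial cross-correlation over all unordered cell-type pairs.

    Self-pairs are included (the diagonal is spatial autocorrelation and is
    not forced to one). Constant cell-type columns yield missing entries.
    """
    types = ds.cell_types
    if len(types) < 2:
        raise InvalidArgumentError("need at least 2 cell types")
    vals = ds.proportions.to_numpy(dtype=float)
    if (vals.std(axis=0) == 0).any():
        bad = [t for t, s in zip(types, vals.std(axis=0)) if s == 0]
        warnings.warn(f"constant cell types give missing SCC: {bad}", stacklevel=2)
    scc = _scc_matrix_from_values(vals, g)
    return CrossCorrelationResult(
        scc=pd.DataFrame(scc, index=types, columns=types), sample_id=ds.sample_id
    )


def _triu_pairs(t: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(t)


def scc_permutation_test(
    ds: SpatialDataset,
    g: AdjacencyGraph,
    n_perm: int = 100,
    seed: int = 0,
) -> CrossCorrelationResult:
    """Permutation significance of the SCC matrix.

    Spot labels are permuted over the fixed graph ``n_perm`` times; the
    one-sided p-value for each pair is ``(1 + #{perm SCC >= observed}) /
    (1 + n_perm)``, and q-values are Benjamini-Hochberg over the
    T(T+1)/2 unordered pairs within the sample.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    res = scc_matrix(ds, g)
    vals = ds.proportions.to_numpy(dtype=float)
    obs = res.scc.to_numpy()
    t = obs.shape[0]
    rng = np.random.default_rng(seed)
    count_ge = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(vals.shape[0])
        perm_scc = _scc_matrix_from_values(vals[perm], g)
        count_ge += (perm_scc >= obs).astype(float)
    p = (1.0 + count_ge) / (1.0 + n_perm)
    p[np.isnan(obs)] = np.nan

    iu, ju = _triu_pairs(t)
    pvec = p[iu, ju]
    qvec = np.full_like(pvec, np.nan)
    ok = ~np.isnan(pvec)
    if ok.any():
        qvec[ok] = bh_adjust(pvec[ok])
    q = np.full_like(p, np.nan)
    q[iu, ju] = qvec
    q[ju, iu] = qvec

    types = res.scc.index
    res.p = pd.DataFrame(p, index=types, columns=types)
    res.q = pd.DataFrame(q, index=types, columns=types)
    return res


def pool_across_samples(
    results: list[CrossCorrelationResult],
    use_adjusted: bool = True,
    normalize_by_spots: bool = False,
    spot_counts: list[int] | None = None,
) -> CrossCorrelationResult:
    """Fisher-combine per-sample significance and average the SCC matrices.

    Per pair, ``X^2 = -2 sum_s ln q_s`` over the samples where the pair is
    defined is referred to a chi-square with 2k degrees of freedom. With
    ``use_adjusted`` (the default) per-sample BH-adjusted values are pooled;
    otherwise raw permutation p-values are pooled and BH is applied to the
    pooled values. Pairs with pooled p below 0.05 are flagged significant.
    """
    if not results:
        raise InvalidArgumentError("need at least one sample result")
    types: list[str] = []
    for r in results:
        for t in r.scc.index:
            if t not in types:
                types.append(t)
    T = len(types)
    scc_stack = np.full((len(results), T, T), np.nan)
    sig_stack = np.full((len(results), T, T), np.nan)
    for s, r in enumerate(results):
        src = r.q if use_adjusted else r.p
        if src is None:
            raise InvalidArgumentError("run scc_permutation_test first")
        scc_stack[s] = r.scc.reindex(index=types, columns=types).to_numpy()
        if normalize_by_spots:
            if spot_counts is None:
                raise InvalidArgumentError("spot_counts required for normalization")
            scc_stack[s] /= spot_counts[s]
        sig_stack[s] = src.reindex(index=types, columns=types).to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_scc = np.nanmean(scc_stack, axis=0)

    pooled = np.full((T, T), np.nan)
    for i in range(T):
        for j in range(i, T):
            qs = sig_stack[:, i, j]
            qs = qs[~np.isnan(qs)]
            if qs.size == 0:
                continue
            x2 = -2.0 * np.sum(np.log(np.clip(qs, 1e-300, 1.0)))
            pooled[i, j] = pooled[j, i] = stats.chi2.sf(x2, df=2 * qs.size)
    if not use_adjusted:
        iu, ju = _triu_pairs(T)
        vec = pooled[iu, ju]
        ok = ~np.isnan(vec)
        adj = np.full_like(vec, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(vec[ok])
        pooled = np.full((T, T), np.nan)
        pooled[iu, ju] = adj
        pooled[ju, iu] = adj

    idx = pd.Index(types)
    return CrossCorrelationResult(
        scc=pd.DataFrame(mean_scc, index=idx, columns=idx),
        pooled_p=pd.DataFrame(pooled, index=idx, columns=idx),
        significant=pd.DataFrame(pooled < 0.05, index=idx, columns=idx),
    )


def cluster_scc(
    pooled: CrossCorrelationResult, k: int = 3, linkage: str = "ward"
) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of cell types on their SCC rows.

    Missing entries are imputed as 0 (with a warning). Returns the cell-type
    to cluster-id mapping and the linkage matrix.
    """
    mat = pooled.scc.to_numpy(dtype=float).copy()
    T = mat.shape[0]
    if k > T:
        raise InvalidArgumentError(f"k={k} exceeds the {T} cell types")
    if np.isnan(mat).any():
        warnings.warn("imputing missing SCC entries as 0", stacklevel=2)
        mat = np.nan_to_num(mat, nan=0.0)
    tree = hierarchy.linkage(pdist(mat, metric="euclidean"), method=linkage)
    membership = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(membership, index=pooled.scc.index, name="cluster"), tree
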