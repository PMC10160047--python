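"""Tissue-state gene signatures and enrichment scoring.

Pseudobulk aggregation, negative-binomial Wald differential expression with
median-of-ratios size factors, Benjamini-Hochberg adjustment, derivation of
unique per-state signatures, and three rank-based enrichment scorers
(single-sample ssGSEA, GSVA-style scoring, pre-ranked GSEA with a
permutation null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tissuestates._errors import InvalidArgumentError
from tissuestates.synthetic import AnnotatedCountMatrix


@dataclass
class PseudobulkMatrix:
    """Gene x sample integer counts with per-sample metadata."""

    counts: pd.DataFrame  # genes x samples, integer
    sample_meta: pd.DataFrame  # state, batch

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise InvalidArgumentError("pseudobulk counts must be integers >= 0")


@dataclass
class DEResult:
    """Per-gene Wald test results for one two-state contrast."""

    table: pd.DataFrame  # gene index; log2_fold_change, wald_statistic, p_value, q_value
    contrast: tuple[str, str]
    size_factors: pd.Series
    dispersions: pd.Series


@dataclass(frozen=True)
class GeneSignature:
    """Ordered, uniqueness-filtered gene list for one tissue state."""

    state: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) > 150:
            raise InvalidArgumentError("signature longer than 150 genes")


@dataclass
class GSEAResult:
    """Pre-ranked GSEA outcome for a single gene set."""

    es: float
    nes: float
    p_value: float
    q_value: float | None
    n_permutations: int
    leading_edge: tuple[str, ...]


# ---------------------------------------------------------------------------
# Pseudobulk and DE
# ---------------------------------------------------------------------------


def pseudobulk(
    matrix: AnnotatedCountMatrix,
    normalized: np.ndarray | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> PseudobulkMatrix:
    """Sum (normalized) counts per sample and round half-up.

    ``normalized`` defaults to the raw counts; it must be gene x nucleus and
    aligned with the matrix. Rounding is half-up (2.5 -> 3).
    """
    vals = matrix.counts if normalized is None else np.asarray(normalized, float)
    if vals.shape != matrix.counts.shape:
        raise InvalidArgumentError("normalized shape must match counts")
    samples = matrix.nucleus_meta["sample_id"].to_numpy()
    uniq = sorted(set(samples))
    agg = np.column_stack([vals[:, samples == s].sum(axis=1) for s in uniq])
    agg = np.floor(agg + 0.5).astype(np.int64)  # half-up
    counts = pd.DataFrame(agg, index=matrix.gene_ids, columns=uniq)
    if sample_meta is None:
        sample_meta = pd.DataFrame(index=pd.Index(uniq, name="sample_id"))
    return PseudobulkMatrix(counts=counts, sample_meta=sample_meta)


def size_factors(pb: PseudobulkMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Uses genes with nonzero counts in every sample: each sample's factor is
    the median ratio of its counts to the per-gene geometric means.
    """
    c = pb.counts.to_numpy(dtype=float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise InvalidArgumentError(
            "no gene has nonzero counts in all samples; consider a pseudocount"
        )
    ref = c[allpos]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo)
    return pd.Series(np.median(ratios, axis=0), index=pb.counts.columns, name="size_factor")


def _fit_dispersions(norm_counts: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion alpha (Var = mu + alpha mu^2), trend-shrunk.

    Method-of-moments estimate per gene, shrunk halfway (in log space)
    toward a lowess trend on log mean.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    m = norm_counts.mean(axis=1)
    v = norm_counts.var(axis=1, ddof=1)
    m_safe = np.maximum(m, 1e-8)
    raw = np.maximum((v - m) / m_safe**2, 1e-8)
    ok = m > 0
    if ok.sum() >= 10:
        fit = lowess(
            np.log(raw[ok]), np.log(m_safe[ok]), frac=0.5, return_sorted=False
        )
        trend = np.full(len(raw), np.log(raw[ok]).mean())
        trend[ok] = fit
    else:
        trend = np.full(len(raw), np.log(raw).mean())
    return np.exp(0.5 * np.log(raw) + 0.5 * trend)


def _batched_nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Fit NB log-linear models for all genes at once via IRLS.

    y: genes x samples; X: samples x p (shared design); offsets: samples
    (log size factors); alpha: per-gene dispersion. Returns (beta, cov).
    """
    G, n = y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.maximum(y.mean(axis=1), 0.1)) - offsets.mean()
    eye = 1e-8 * np.eye(p)
    for _ in range(max_iter):
        eta = beta @ X.T + offsets  # G x n
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)  # working weights
        z = eta - offsets + (y - mu) / np.maximum(mu, 1e-12)
        XtW = X.T[None, :, :] * w[:, None, :]  # G x p x n
        A = XtW @ X + eye
        b = np.einsum("gpn,gn->gp", XtW, z)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    eta = beta @ X.T + offsets
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    info = np.einsum("np,gn,nq->gpq", X, w, X) + eye
    cov = np.linalg.inv(info)
    return beta, cov


def nb_wald_de(
    pb: PseudobulkMatrix,
    groups: pd.Series,
    batch: pd.Series | None,
    contrast: tuple[str, str],
) -> DEResult:
    """NB Wald test between two tissue states, controlling for batch.

    Per gene, ``mu = s_j exp(b0 + b_state + b_batch)`` with median-of-ratios
    size factors and trend-shrunk method-of-moments dispersions; the Wald
    statistic is the state coefficient over its standard error with a
    two-sided normal reference, and q-values are Benjamini-Hochberg.
    """
    x_state, y_state = contrast
    groups = groups.reindex(pb.counts.columns)
    keep = groups.isin(contrast).to_numpy()
    if keep.sum() < 4 or (groups[keep] == x_state).sum() < 2 or (
        groups[keep] == y_state
    ).sum() < 2:
        raise InvalidArgumentError("need >= 2 samples per contrasted state")
    sub = PseudobulkMatrix(
        counts=pb.counts.loc[:, keep], sample_meta=pb.sample_meta.loc[keep]
    )
    sf = size_factors(sub)
    y = sub.counts.to_numpy(dtype=float)
    n = y.shape[1]

    is_x = (groups[keep] == x_state).to_numpy().astype(float)
    cols = [np.ones(n), is_x]
    names = ["intercept", "state"]
    if batch is not None:
        b = batch.reindex(pb.counts.columns)[keep]
        for lev in sorted(set(b))[1:]:
            cols.append((b == lev).to_numpy().astype(float))
            names.append(f"batch[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidArgumentError(
            "singular design: batch is confounded with state"
        )

    offsets = np.log(sf.to_numpy())
    alpha = _fit_dispersions(y / sf.to_numpy()[None, :])
    beta, cov = _batched_nb_irls(y, X, offsets, alpha)
    b_state = beta[:, 1]
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    wald = b_state / se
    pvals = 2 * stats.norm.sf(np.abs(wald))
    # flat genes: zero variance across samples gives no evidence either way
    flat = y.std(axis=1) == 0
    wald[flat] = 0.0
    pvals[flat] = 1.0
    table = pd.DataFrame(
        {
            "log2_fold_change": b_state / np.log(2),
            "wald_statistic": wald,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
        },
        index=sub.counts.index,
    )
    return DEResult(
        table=table,
        contrast=contrast,
        size_factors=sf,
        dispersions=pd.Series(alpha, index=sub.counts.index, name="dispersion"),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def derive_state_signatures(
    de_ab: DEResult,
    de_ac: DEResult,
    de_bc: DEResult,
    q_cut: float = 0.05,
    top_n: int = 150,
) -> dict[str, GeneSignature]:
    """Unique per-state signatures from the three pairwise contrasts.

    A gene joins state X's candidate set when it is significantly up
    (q < ``q_cut``, log2FC > 0 toward X) in both of X's contrasts. Genes
    appearing in two states' candidate sets are removed from both; survivors
    are ranked by mean log2FC over the supporting contrasts and truncated to
    ``top_n``.
    """
    results = {de.contrast: de for de in (de_ab, de_ac, de_bc)}
    states = sorted({s for c in results for s in c})
    if len(states) != 3:
        raise InvalidArgumentError("expected contrasts among exactly 3 states")
    universe = de_ab.table.index
    for de in (de_ac, de_bc):
        if not de.table.index.equals(universe):
            raise InvalidArgumentError("DE results must share a gene universe")

    def up_table(x: str, y: str) -> pd.DataFrame:
        """log2FC toward x and q for the (x, y) contrast, whichever way stored."""
        if (x, y) in results:
            t = results[(x, y)].table
            return t[["log2_fold_change", "q_value"]]
        t = results[(y, x)].table
        out = t[["log2_fold_change", "q_value"]].copy()
        out["log2_fold_change"] = -out["log2_fold_change"]
        return out

    candidates: dict[str, pd.Series] = {}
    for x in states:
        others = [s for s in states if s != x]
        t1, t2 = up_table(x, others[0]), up_table(x, others[1])
        ok = (
            (t1["q_value"] < q_cut)
            & (t1["log2_fold_change"] > 0)
            & (t2["q_value"] < q_cut)
            & (t2["log2_fold_change"] > 0)
        )
        mean_lfc = (t1["log2_fold_change"] + t2["log2_fold_change"]) / 2
        candidates[x] = mean_lfc[ok]

    signatures: dict[str, GeneSignature] = {}
    for x in states:
        other_genes: set[str] = set()
        for yst in states:
            if yst != x:
                other_genes |= set(candidates[yst].index)
        unique = candidates[x].drop(
            index=[g for g in candidates[x].index if g in other_genes]
        )
        if unique.empty:
            warnings.warn(f"state {x}: empty signature", stacklevel=2)
        ordered = unique.sort_values(ascending=False).index[:top_n]
        signatures[x] = GeneSignature(state=x, genes=tuple(ordered))
    return signatures


# ---------------------------------------------------------------------------
# Enrichment scoring
# ---------------------------------------------------------------------------


def _check_sets(
    gene_sets: dict[str, list], genes: pd.Index
) -> dict[str, np.ndarray]:
    present: dict[str, np.ndarray] = {}
    pos = {g: i for i, g in enumerate(genes)}
    for name, members in gene_sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set {name} has no genes in matrix; dropped",
                          stacklevel=3)
            continue
        present[name] = idx
    if not present:
        raise InvalidArgumentError("no usable gene set")
    return present


def ssgsea(
    expr: pd.DataFrame,
    gene_sets: dict[str, list],
    tau: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA scores (sample x gene set).

    Per sample, genes are ranked by expression (descending; ties broken by
    input order) and scored with the weighted running-sum statistic: the
    enrichment score is the sum over all positions of the difference between
    the |rank|^tau-weighted in-set CDF and the uniform out-of-set CDF. With
    ``normalize``, scores are divided by the global max - min.
    """
    if expr.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 genes")
    sets = _check_sets(gene_sets, expr.index)
    vals = expr.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    rank_weight = np.arange(n_genes, 0, -1, dtype=float) ** tau

    out = np.zeros((n_samples, len(sets)))
    set_names = list(sets)
    in_mask = np.zeros((len(sets), n_genes), dtype=bool)
    for k, name in enumerate(set_names):
        in_mask[k, sets[name]] = True
    for j in range(n_samples):
        order = np.argsort(-vals[:, j], kind="stable")
        for k in range(len(set_names)):
            mask = in_mask[k][order]
            w = np.where(mask, rank_weight, 0.0)
            denom_in = w.sum()
            n_out = n_genes - mask.sum()
            if n_out == 0:
                out[j, k] = 0.0
                continue
            p_in = np.cumsum(w) / denom_in
            p_out = np.cumsum(~mask) / n_out
            out[j, k] = float(np.sum(p_in - p_out))
    scores = pd.DataFrame(out, index=expr.columns, columns=set_names)
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return scores


def gsva_scores(
    expr: pd.DataFrame,
    gene_sets: dict[str, list],
    kcdf: str = "gaussian",
    mx_diff: bool = True,
) -> pd.DataFrame:
    """GSVA-style scores using a Gaussian-kernel CDF across samples.

    Each gene's expression is transformed to a relative statistic via a
    Gaussian-kernel CDF over samples (bandwidth sd/4). Per sample, genes are
    ordered by the statistic and walked with a symmetric-rank-weighted
    KS-like statistic; with ``mx_diff`` the score is the signed sum of the
    maximum positive and negative deviations, else the largest |deviation|.
    """
    if kcdf.lower() != "gaussian":
        raise InvalidArgumentError("only the gaussian kernel is supported")
    n_genes, n_samples = expr.shape
    if n_samples < 3:
        raise InvalidArgumentError("need >= 3 samples for kernel estimation")
    sets = _check_sets(gene_sets, expr.index)
    x = expr.to_numpy(dtype=float)

    sd = x.std(axis=1, ddof=1)
    h = np.maximum(sd / 4.0, 1e-12)
    # z[g, j] = mean_k Phi((x[g,j] - x[g,k]) / h_g)
    diff = (x[:, :, None] - x[:, None, :]) / h[:, None, None]
    z = stats.norm.cdf(diff).mean(axis=2)

    set_names = list(sets)
    out = np.zeros((n_samples, len(set_names)))
    for j in range(n_samples):
        order = np.argsort(-z[:, j], kind="stable")
        # symmetric rank statistic: largest at both extremes of the ordering
        r = np.abs(n_genes / 2.0 - np.arange(1, n_genes + 1))
        for k, name in enumerate(set_names):
            mask = np.zeros(n_genes, dtype=bool)
            mask[sets[name]] = True
            mask = mask[order]
            n_in = mask.sum()
            n_out = n_genes - n_in
            if n_out == 0:
                out[j, k] = 0.0
                continue
            w = np.where(mask, r, 0.0)
            nu = np.cumsum(w) / max(w.sum(), 1e-300) - np.cumsum(~mask) / n_out
            if mx_diff:
                out[j, k] = float(nu.max(initial=0.0) + nu.min(initial=0.0))
            else:
                out[j, k] = float(nu[np.argmax(np.abs(nu))])
    return pd.DataFrame(out, index=expr.columns, columns=set_names)


def _running_es(
    metric_sorted: np.ndarray, hit_mask: np.ndarray, weight_p: float
) -> tuple[np.ndarray, float, int]:
    """Weighted KS running sum; returns (walk, ES, extremum position)."""
    n = len(metric_sorted)
    n_set = int(hit_mask.sum())
    if n_set == n:
        return np.zeros(n), 0.0, 0
    w = np.abs(metric_sorted) ** weight_p
    w = np.where(hit_mask, w, 0.0)
    denom = w.sum()
    if denom == 0:  # all-zero metric inside the set: fall back to uniform hits
        w = hit_mask.astype(float)
        denom = w.sum()
    steps = w / denom - (~hit_mask) / (n - n_set)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return walk, float(walk[i]), i


def preranked_gsea(
    metric: pd.Series,
    gene_set: list,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> GSEAResult:
    """Pre-ranked GSEA with a random-gene-set permutation null.

    Genes are sorted by the metric (descending); hits step up by
    |metric|^p normalized over the set, misses step down uniformly. The ES
    is the signed extremum of the running sum. The null re-draws same-size
    random gene sets; NES divides ES by the mean |null ES| of matching sign
    and the one-sided p-value uses the +1 permutation correction.
    """
    metric = metric.sort_values(ascending=False, kind="stable")
    genes = metric.index.to_numpy()
    hit = np.isin(genes, list(gene_set))
    if not hit.any():
        raise InvalidArgumentError("gene set does not intersect the metric")
    vals = metric.to_numpy(dtype=float)
    walk, es, i_ext = _running_es(vals, hit, weight_p)

    if hit.all():
        return GSEAResult(
            es=0.0, nes=0.0, p_value=1.0, q_value=None,
            n_permutations=n_perm, leading_edge=(),
        )

    rng = np.random.default_rng(seed)
    n = len(genes)
    n_set = int(hit.sum())
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=n_set, replace=False)] = True
        _, null_es[b], _ = _running_es(vals, perm_hit, weight_p)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = 0.0
        p = 1.0 / (1 + n_perm)
    else:
        denom = np.abs(null_es[same_sign]).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    p = max(p, 1.0 / (n_perm + 1))

    if es >= 0:
        leading = genes[: i_ext + 1][hit[: i_ext + 1]]
    else:
        leading = genes[i_ext:][hit[i_ext:]]
    return GSEAResult(
        es=es,
        nes=float(nes),
        p_value=float(p),
        q_value=None,
        n_permutations=n_perm,
        leading_edge=tuple(leading),
    )
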