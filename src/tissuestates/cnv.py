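"""Consensus CNV-based neoplastic calling.

Two independent routes label nuclei as CNVpos/CNVneg:

1. a chromosome-level malignancy score — mean log2(count+1) per chromosome,
   PCA-guided selection of gained/lost chromosomes, the gained/lost ratio
   z-scaled per sample, then k-means or normal-outlier labeling;
2. a windowed-expression caller — per-gene relative expression against a
   reference population, smoothed over gene windows in genomic order, with
   per-chromosome threshold calls.

Nuclei on which the two routes disagree are excluded by the consensus rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from tissuestates._errors import EmptySelectionError, InvalidArgumentError
from tissuestates.synthetic import AnnotatedCountMatrix, GenePanel

CNVPOS = "CNVpos"
CNVNEG = "CNVneg"
EXCLUDED = "excluded"

_SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


@dataclass
class ChromosomeProfile:
    """Nucleus x chromosome matrix of mean log2(count + 1)."""

    values: np.ndarray  # nuclei x chromosomes
    chromosomes: list[str]
    nucleus_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidArgumentError("profile values must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.nucleus_ids, columns=self.chromosomes
        )


@dataclass(frozen=True)
class ChromosomeSelection:
    """Gained/lost chromosomes selected by correlation with PC2."""

    gained: tuple[str, ...]
    lost: tuple[str, ...]
    pc2_correlation: pd.Series

    def __post_init__(self):
        if len(self.gained) > 3 or len(self.lost) > 3:
            raise InvalidArgumentError("at most 3 chromosomes per direction")
        if set(self.gained) & set(self.lost):
            raise InvalidArgumentError("gained and lost overlap")


@dataclass
class MalignancyCalls:
    """Per-nucleus malignancy scores and (optionally) CNV labels."""

    nucleus_ids: np.ndarray
    sample_ids: np.ndarray
    raw_score: np.ndarray
    z_score: np.ndarray
    label: np.ndarray | None = None  # CNVpos / CNVneg
    method: str | None = None


@dataclass
class ConsensusCalls:
    """Consensus of two independent callers; disagreements are excluded."""

    nucleus_ids: np.ndarray
    label: np.ndarray  # CNVpos / CNVneg / excluded
    discordant_fraction: float


# ---------------------------------------------------------------------------


def chromosome_profile(
    matrix: AnnotatedCountMatrix, panel: GenePanel
) -> ChromosomeProfile:
    """Average log2(count + 1) across each chromosome for every nucleus."""
    panel_pos = {g: i for i, g in enumerate(panel.gene_ids)}
    missing = [g for g in matrix.gene_ids if g not in panel_pos]
    if missing:
        raise InvalidArgumentError(
            f"gene(s) missing from panel: {missing[:5]}"
        )
    log2c = np.log2(matrix.counts.astype(float) + 1.0)
    chrom_of = dict(zip(panel.gene_ids, panel.chromosomes))
    gene_chroms = np.array([chrom_of[g] for g in matrix.gene_ids])
    chroms = [c for c in panel.chromosome_order if (gene_chroms == c).any()]
    values = np.column_stack(
        [log2c[gene_chroms == c, :].mean(axis=0) for c in chroms]
    )
    return ChromosomeProfile(
        values=values,
        chromosomes=chroms,
        nucleus_ids=matrix.nucleus_ids.copy(),
        sample_ids=matrix.nucleus_meta["sample_id"].to_numpy().copy(),
    )


def _autosome_mask(chromosomes: list[str]) -> np.ndarray:
    return np.array([c not in _SEX_CHROMOSOMES for c in chromosomes])


def select_cnv_chromosomes(
    profile: ChromosomeProfile,
    reference_labels: np.ndarray | None = None,
    correlation_threshold: float = 0.5,
    max_per_direction: int = 3,
    min_pc2_ratio: float = 2.0,
) -> ChromosomeSelection:
    """Select gained/lost chromosomes by their correlation with PC2.

    A centered, unit-variance PCA is run on the nucleus x autosome matrix.
    Chromosomes whose Pearson correlation with the PC2 score vector reaches
    ``correlation_threshold`` in absolute value are kept (at most
    ``max_per_direction`` per direction, ranked by |r|). A selected
    chromosome is called gained if its mean profile value among putative
    aberrant nuclei (upper PC2 tercile, or non-reference nuclei when
    ``reference_labels`` marks CNVneg nuclei as True) exceeds that among the
    remainder, else lost.

    Raises
    ------
    EmptySelectionError
        If no chromosome passes the threshold; callers should fall back to
        a lower threshold or an external chromosome list.
    """
    auto = _autosome_mask(profile.chromosomes)
    if auto.sum() < 2:
        raise InvalidArgumentError("need at least 2 autosomal chromosomes")
    if profile.values.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 nuclei")
    X = profile.values[:, auto]
    chroms = [c for c, a in zip(profile.chromosomes, auto) if a]

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise InvalidArgumentError("fewer than 2 non-constant autosomes")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    chroms = [c for c, k in zip(chroms, keep) if k]

    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    if len(s) < 2:
        raise InvalidArgumentError("rank-deficient profile; no PC2")
    lam = s**2 / Xs.shape[0]
    # a CNV axis makes PC2 stand out from the noise bulk; without that gap,
    # chromosome/PC2 correlations are driven by noise alignment alone
    if len(lam) >= 3 and lam[1] / max(lam[2], 1e-12) < min_pc2_ratio:
        raise EmptySelectionError(
            f"PC2 eigenvalue ({lam[1]:.3g}) does not stand out from the bulk "
            f"({lam[2]:.3g}); no CNV structure detected"
        )
    pc2 = u[:, 1] * s[1]

    r = np.zeros(len(chroms))
    for j in range(len(chroms)):
        r[j] = np.corrcoef(X[:, keep][:, j], pc2)[0, 1]
    # orient PC2 so the strongest-correlated chromosome is positive
    top = int(np.argmax(np.abs(r)))
    if r[top] < 0:
        pc2 = -pc2
        r = -r
    corr = pd.Series(r, index=chroms, name="pc2_correlation")

    passing = [c for c in chroms if abs(corr[c]) >= correlation_threshold]
    if not passing:
        raise EmptySelectionError(
            f"no chromosome reached |r| >= {correlation_threshold}; "
            "lower the threshold or supply a chromosome list"
        )

    if reference_labels is not None:
        aberrant = ~np.asarray(reference_labels, dtype=bool)
    else:
        # candidate aberrant group = one PC2 tercile; pick the tercile whose
        # selected chromosomes deviate more from each nucleus's own autosome
        # average, which identifies the CNV-carrying side of PC2
        Xk = X[:, keep]
        centered = Xk - Xk.mean(axis=1, keepdims=True)
        sel_idx = [chroms.index(c) for c in passing]
        magnitude = np.abs(centered[:, sel_idx]).mean(axis=1)
        upper = pc2 >= np.quantile(pc2, 2.0 / 3.0)
        lower = pc2 <= np.quantile(pc2, 1.0 / 3.0)
        if magnitude[upper].mean() >= magnitude[lower].mean():
            aberrant = upper
        else:
            aberrant = lower
    if aberrant.sum() == 0 or aberrant.sum() == len(aberrant):
        raise InvalidArgumentError("cannot split nuclei into aberrant/rest")

    gained, lost = [], []
    for c in sorted(passing, key=lambda c: -abs(corr[c])):
        j = chroms.index(c)
        col = X[:, keep][:, j]
        if col[aberrant].mean() > col[~aberrant].mean():
            if len(gained) < max_per_direction:
                gained.append(c)
        else:
            if len(lost) < max_per_direction:
                lost.append(c)
    return ChromosomeSelection(
        gained=tuple(gained), lost=tuple(lost), pc2_correlation=corr
    )


def malignancy_score(
    profile: ChromosomeProfile,
    selection: ChromosomeSelection,
    denominator_floor: float = 0.01,
) -> MalignancyCalls:
    """Gained-over-lost chromosome score, z-scaled within each sample.

    ``raw_score = sum(gained columns) / max(sum(lost columns), floor)``.
    The floor keeps scores finite for nuclei with no lost-chromosome signal.
    """
    if not selection.gained or not selection.lost:
        raise InvalidArgumentError("selection needs >= 1 gained and 1 lost")
    col = {c: i for i, c in enumerate(profile.chromosomes)}
    for c in selection.gained + selection.lost:
        if c not in col:
            raise InvalidArgumentError(f"chromosome {c} not in profile")
    num = profile.values[:, [col[c] for c in selection.gained]].sum(axis=1)
    den = profile.values[:, [col[c] for c in selection.lost]].sum(axis=1)
    raw = num / np.maximum(den, denominator_floor)

    z = np.zeros_like(raw)
    for s in np.unique(profile.sample_ids):
        m = profile.sample_ids == s
        mu = raw[m].mean()
        sd = raw[m].std(ddof=1) if m.sum() > 1 else 0.0
        if sd == 0:
            warnings.warn(
                f"constant malignancy scores in sample {s}; z set to 0",
                stacklevel=2,
            )
            z[m] = 0.0
        else:
            z[m] = (raw[m] - mu) / sd
    return MalignancyCalls(
        nucleus_ids=profile.nucleus_ids.copy(),
        sample_ids=profile.sample_ids.copy(),
        raw_score=raw,
        z_score=z,
    )


def _kmeans_1d(x: np.ndarray, seed: int, n_init: int = 10) -> np.ndarray:
    """2-means on a 1-D array; returns boolean membership of the higher-mean cluster."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    lab = km.fit_predict(x.reshape(-1, 1))
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    return lab == hi


def _outlier_right(x: np.ndarray, rho: float) -> np.ndarray:
    """Right-tail outliers under a normal fitted to the central 5-95% band.

    Flags observations above the point z* where the fitted model's expected
    number of observations >= z* drops below ``rho``.
    """
    lo, hi = np.quantile(x, [0.05, 0.95])
    band = x[(x >= lo) & (x <= hi)]
    mu, sd = band.mean(), band.std(ddof=1)
    if sd == 0:
        return np.zeros(len(x), dtype=bool)
    n = len(x)
    zstar = mu + sd * stats.norm.ppf(1.0 - rho / n)
    return x > zstar


def call_neoplastic(
    calls: MalignancyCalls,
    method: str = "kmeans",
    rho: float = 0.1,
    seed: int = 0,
) -> MalignancyCalls:
    """Label nuclei CNVpos/CNVneg from z-scored malignancy scores.

    ``kmeans``: per-sample 2-means on z-scores; the higher-mean cluster is
    CNVpos. ``outlier``: per-sample right-tail outlier detection under a
    normal fitted to the central quantile band. Samples with constant
    scores are labelled all-CNVneg with a warning (no bimodality).
    """
    if method not in ("kmeans", "outlier"):
        raise InvalidArgumentError(f"unknown method: {method}")
    labels = np.full(len(calls.z_score), CNVNEG, dtype=object)
    for s in np.unique(calls.sample_ids):
        m = calls.sample_ids == s
        z = calls.z_score[m]
        if m.sum() < 4:
            raise InvalidArgumentError(
                f"sample {s} has {int(m.sum())} nuclei; need >= 4"
            )
        if np.ptp(z) == 0:
            warnings.warn(
                f"sample {s}: constant scores, labelling all CNVneg",
                stacklevel=2,
            )
            continue
        if method == "kmeans":
            pos = _kmeans_1d(z, seed=seed)
        else:
            pos = _outlier_right(z, rho=rho)
        lab = labels[m]
        lab[pos] = CNVPOS
        labels[m] = lab
    return replace(calls, label=labels.astype(str), method=method)


def _moving_average_truncated(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with windows truncated at the ends."""
    n = a.shape[0]
    csum = np.cumsum(np.vstack([np.zeros((1,) + a.shape[1:]), a]), axis=0)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo).reshape((-1,) + (1,) * (a.ndim - 1))


def windowed_cnv_profile(
    matrix: AnnotatedCountMatrix,
    panel: GenePanel,
    reference_ids: set[str],
    window: int = 100,
    call_threshold: float = 0.15,
    center_nuclei: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Windowed relative-expression CNV caller.

    Per-gene log2(count+1) is referenced to the mean over ``reference_ids``
    nuclei (and, with ``center_nuclei``, additionally centered within each
    nucleus so that library-depth offsets do not mimic genome-wide CNVs),
    smoothed with a centered ``window``-gene moving average in
    genomic order within each chromosome, and averaged per chromosome. A
    chromosome is called gained (lost) when its mean smoothed value exceeds
    +``call_threshold`` (falls below -``call_threshold``); a nucleus is
    CNVpos iff at least one chromosome is called.

    Returns the per-nucleus label series and the nucleus x chromosome table
    of mean smoothed values.
    """
    if window < 2:
        raise InvalidArgumentError("window must be >= 2")
    if not reference_ids:
        raise InvalidArgumentError("reference_ids must be nonempty")
    ids = matrix.nucleus_ids
    ref_mask = np.isin(ids, list(reference_ids))
    if not ref_mask.any():
        raise InvalidArgumentError("no reference nucleus found in matrix")
    if ref_mask.all():
        warnings.warn(
            "reference set covers every nucleus; calls will be near-null",
            stacklevel=2,
        )

    log2c = np.log2(matrix.counts.astype(float) + 1.0)
    rel = log2c - log2c[:, ref_mask].mean(axis=1, keepdims=True)
    if center_nuclei:
        rel = rel - rel.mean(axis=0, keepdims=True)

    chrom_of = dict(zip(panel.gene_ids, panel.chromosomes))
    pos_of = dict(zip(panel.gene_ids, panel.position_index))
    gene_chroms = np.array([chrom_of.get(g) for g in matrix.gene_ids])
    if any(c is None for c in gene_chroms):
        missing = matrix.gene_ids[np.equal(gene_chroms, None)][:5]
        raise InvalidArgumentError(f"gene(s) missing from panel: {list(missing)}")
    gene_pos = np.array([pos_of[g] for g in matrix.gene_ids])

    chroms = [c for c in panel.chromosome_order if (gene_chroms == c).any()]
    chrom_means = np.zeros((matrix.n_nuclei, len(chroms)))
    for j, c in enumerate(chroms):
        sel = np.flatnonzero(gene_chroms == c)
        sel = sel[np.argsort(gene_pos[sel], kind="stable")]
        w = window
        if len(sel) < window:
            warnings.warn(
                f"chromosome {c} has {len(sel)} genes < window {window}; "
                "using full-chromosome window",
                stacklevel=2,
            )
            w = len(sel)
        smoothed = _moving_average_truncated(rel[sel, :], w)
        chrom_means[:, j] = smoothed.mean(axis=0)

    called = (chrom_means > call_threshold) | (chrom_means < -call_threshold)
    labels = np.where(called.any(axis=1), CNVPOS, CNVNEG)
    return (
        pd.Series(labels, index=ids, name="label"),
        pd.DataFrame(chrom_means, index=ids, columns=chroms),
    )


def consensus_calls(
    labels_a: pd.Series | np.ndarray,
    labels_b: pd.Series | np.ndarray,
    nucleus_ids: np.ndarray | None = None,
) -> ConsensusCalls:
    """Keep labels where two callers agree; exclude discordant nuclei."""
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if set(labels_a.index) != set(labels_b.index):
            raise InvalidArgumentError("mismatched nucleus sets")
        labels_b = labels_b.reindex(labels_a.index)
        nucleus_ids = labels_a.index.to_numpy()
        a, b = labels_a.to_numpy(), labels_b.to_numpy()
    else:
        a = np.asarray(labels_a)
        b = np.asarray(labels_b)
        if len(a) != len(b):
            raise InvalidArgumentError("mismatched nucleus sets")
        if nucleus_ids is None:
            nucleus_ids = np.arange(len(a))
    agree = a == b
    label = np.where(agree, a, EXCLUDED)
    return ConsensusCalls(
        nucleus_ids=np.asarray(nucleus_ids),
        label=label.astype(str),
        discordant_fraction=float((~agree).mean()),
    )


def calls_from_malignancy(calls: MalignancyCalls) -> pd.Series:
    """Labels of a labelled MalignancyCalls as a nucleus-indexed series."""
    if calls.label is None:
        raise InvalidArgumentError("calls are unlabelled; run call_neoplastic")
    return pd.Series(calls.label, index=calls.nucleus_ids, name="label")
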