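"""Compositional tissue-state analysis.

Builds per-sample cell-state composition matrices (glioma states collapsed
into a CNVpos total, with glioma-state fractions kept as supplementary
variables), runs PCA with supplementary quantitative variables, clusters
samples into tissue states, and assigns new samples by nearest centroid.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist

from tissuestates._errors import InvalidArgumentError
from tissuestates.synthetic import GLIOMA_STATES, NON_NEOPLASTIC_STATES

CNVPOS_COLUMN = "CNVpos"

#: Active variables of the composition matrix: 12 non-neoplastic states + CNVpos.
ACTIVE_COLUMNS: tuple[str, ...] = NON_NEOPLASTIC_STATES + (CNVPOS_COLUMN,)


@dataclass
class CompositionMatrix:
    """Sample x cell-state fractions.

    ``active`` holds the 12 non-neoplastic state fractions plus the CNVpos
    total (rows sum to 1); ``supplementary`` holds glioma-state fractions
    within CNVpos nuclei (rows sum to 1, or all-zero when CNVpos = 0).
    """

    active: pd.DataFrame
    supplementary: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        sums = self.active.to_numpy().sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise InvalidArgumentError("active rows must sum to 1")
        ssum = self.supplementary.to_numpy().sum(axis=1)
        bad = (np.abs(ssum - 1.0) > 1e-9) & (np.abs(ssum) > 1e-9)
        if np.any(bad):
            raise InvalidArgumentError(
                "supplementary rows must sum to 1 or be all-zero"
            )


@dataclass
class PCAResult:
    """PCA of the active composition with supplementary variable coordinates.

    Variable coordinates are Pearson correlations of each variable with the
    component score vectors (the supplementary variables do not influence
    the axes; their coordinates are computed post hoc the same way).
    """

    eigenvalues: pd.Series
    scores: pd.DataFrame  # sample x component
    variable_coordinates: pd.DataFrame  # active variable x component
    supplementary_coordinates: pd.DataFrame
    loadings: pd.DataFrame  # active variable x component (unit right-singular)


@dataclass
class TissueStateAssignment:
    """Tissue-state partition of samples with centroids and merge tree."""

    states: pd.Series  # sample -> state letter
    centroids: pd.DataFrame  # state x active variable
    linkage_tree: np.ndarray
    distance: str


# ---------------------------------------------------------------------------


def composition_matrix(annotations: pd.DataFrame) -> CompositionMatrix:
    """Per-sample cell-state fractions from per-nucleus annotations.

    ``annotations`` needs columns ``sample_id``, ``state`` and (optionally)
    ``cnv_label``; a nucleus counts as CNVpos if its CNV label says so or its
    state is a glioma state. Active fractions are of all nuclei in the
    sample; supplementary glioma-state fractions are of CNVpos nuclei only.
    """
    required = {"sample_id", "state"}
    if not required <= set(annotations.columns):
        raise InvalidArgumentError(f"annotations need columns {sorted(required)}")
    if annotations["state"].isna().any():
        raise InvalidArgumentError("every nucleus must carry a state label")
    glioma = set(GLIOMA_STATES)
    ann = annotations.copy()
    if "cnv_label" in ann.columns:
        is_pos = ann["cnv_label"].to_numpy() == "CNVpos"
    else:
        is_pos = ann["state"].isin(glioma).to_numpy()
    ann["_cnvpos"] = is_pos

    active_rows, supp_rows, meta_rows, samples = [], [], [], []
    for sample, grp in ann.groupby("sample_id", sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"sample {sample} has no nuclei; dropped", stacklevel=2)
            continue
        counts = grp.loc[~grp["_cnvpos"], "state"].value_counts()
        row = {s: counts.get(s, 0) / n for s in NON_NEOPLASTIC_STATES}
        row[CNVPOS_COLUMN] = grp["_cnvpos"].sum() / n
        # fold any unrecognized non-neoplastic label into the nearest bucket
        unknown = set(counts.index) - set(NON_NEOPLASTIC_STATES)
        if unknown:
            raise InvalidArgumentError(
                f"unknown non-neoplastic state(s) in {sample}: {sorted(unknown)}"
            )
        active_rows.append(row)
        pos = grp.loc[grp["_cnvpos"], "state"].value_counts()
        npos = grp["_cnvpos"].sum()
        supp_rows.append(
            {s: (pos.get(s, 0) / npos if npos else 0.0) for s in GLIOMA_STATES}
        )
        meta_rows.append(
            {"condition": grp["condition"].iloc[0]}
            if "condition" in grp.columns
            else {}
        )
        samples.append(sample)

    idx = pd.Index(samples, name="sample_id")
    return CompositionMatrix(
        active=pd.DataFrame(active_rows, index=idx)[list(ACTIVE_COLUMNS)],
        supplementary=pd.DataFrame(supp_rows, index=idx)[list(GLIOMA_STATES)],
        sample_meta=pd.DataFrame(meta_rows, index=idx),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pca_with_supplementary(comp: CompositionMatrix) -> PCAResult:
    """PCA on standardized active fractions, supplementary vars projected.

    Active columns are centered and scaled to unit (population) variance, so
    eigenvalues sum to the number of retained active variables. Variable and
    supplementary coordinates are correlations with the component scores;
    each component's sign is fixed so its largest-|coordinate| variable is
    positive.
    """
    X = comp.active.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise InvalidArgumentError("need at least 3 samples for PCA")
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping constant active variables: "
            f"{list(comp.active.columns[const])}",
            stacklevel=2,
        )
    cols = comp.active.columns[~const]
    Xs = (X[:, ~const] - X[:, ~const].mean(axis=0)) / sd[~const]

    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    eigenvalues = s**2 / n
    ncomp = int((eigenvalues > 1e-12).sum())
    comp_names = [f"PC{k + 1}" for k in range(ncomp)]
    scores = u[:, :ncomp] * s[:ncomp]
    loadings = vt[:ncomp].T

    var_coord = np.array(
        [
            [_safe_corr(Xs[:, j], scores[:, k]) for k in range(ncomp)]
            for j in range(len(cols))
        ]
    )
    supp = comp.supplementary.to_numpy(dtype=float)
    supp_coord = np.array(
        [
            [_safe_corr(supp[:, j], scores[:, k]) for k in range(ncomp)]
            for j in range(supp.shape[1])
        ]
    )

    for k in range(ncomp):
        j = int(np.nanargmax(np.abs(var_coord[:, k])))
        if var_coord[j, k] < 0:
            var_coord[:, k] *= -1
            supp_coord[:, k] *= -1
            scores[:, k] *= -1
            loadings[:, k] *= -1

    return PCAResult(
        eigenvalues=pd.Series(eigenvalues[:ncomp], index=comp_names),
        scores=pd.DataFrame(scores, index=comp.active.index, columns=comp_names),
        variable_coordinates=pd.DataFrame(
            var_coord, index=cols, columns=comp_names
        ),
        supplementary_coordinates=pd.DataFrame(
            supp_coord, index=comp.supplementary.columns, columns=comp_names
        ),
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_names),
    )


def _name_clusters(
    active: pd.DataFrame, membership: np.ndarray, k: int
) -> dict[int, str]:
    """Map raw cluster ids to letters: A = most neuronal, C = most CNVpos.

    Clusters are ordered by ascending mean CNVpos fraction, then the cluster
    with the highest mean Neuron fraction is moved to the front; letters are
    assigned in that order (A, B, C, ...).
    """
    ids = sorted(set(membership))
    mean_cnv = {
        cid: active.loc[membership == cid, CNVPOS_COLUMN].mean() for cid in ids
    }
    mean_neu = {cid: active.loc[membership == cid, "Neuron"].mean() for cid in ids}
    order = sorted(ids, key=lambda cid: mean_cnv[cid])
    top_neuron = max(ids, key=lambda cid: mean_neu[cid])
    order.remove(top_neuron)
    order.insert(0, top_neuron)
    letters = string.ascii_uppercase
    return {cid: letters[i] for i, cid in enumerate(order)}


_LINKAGE_FOR_METRIC = {"manhattan": "average", "euclidean": "average"}


def cluster_tissue_states(
    comp: CompositionMatrix,
    k: int = 3,
    distance: str = "manhattan",
    linkage: str | None = None,
) -> TissueStateAssignment:
    """Agglomerative clustering of samples on their active compositions.

    Pairwise distances (Manhattan by default) feed average-linkage
    agglomeration; the tree is cut to ``k`` clusters. Clusters are named
    A/B/C by composition: A has the highest mean Neuron fraction, C the
    highest mean CNVpos fraction.
    """
    if distance not in ("manhattan", "euclidean"):
        raise InvalidArgumentError(f"unsupported distance: {distance}")
    n = len(comp.active)
    if n < k:
        raise InvalidArgumentError(f"{n} samples < k={k}")
    linkage = linkage or _LINKAGE_FOR_METRIC[distance]
    metric = "cityblock" if distance == "manhattan" else "euclidean"
    d = pdist(comp.active.to_numpy(dtype=float), metric=metric)
    tree = hierarchy.linkage(d, method=linkage)
    membership = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    names = _name_clusters(comp.active, membership, k)
    states = pd.Series(
        [names[c] for c in membership], index=comp.active.index, name="state"
    )
    centroids = (
        comp.active.groupby(states).mean().sort_index()
    )
    centroids.index.name = "state"
    return TissueStateAssignment(
        states=states, centroids=centroids, linkage_tree=tree, distance=distance
    )


def assign_new_samples(
    comp_new: CompositionMatrix, assignment: TissueStateAssignment
) -> pd.Series:
    """Assign each new sample the tissue state of its nearest centroid.

    Uses the same distance metric as the original clustering; ties go to
    the alphabetically first state.
    """
    cols = list(assignment.centroids.columns)
    if list(comp_new.active.columns) != cols:
        raise InvalidArgumentError("active variable sets differ")
    metric = "cityblock" if assignment.distance == "manhattan" else "euclidean"
    cent = assignment.centroids.sort_index()
    d = cdist(comp_new.active.to_numpy(dtype=float), cent.to_numpy(), metric=metric)
    nearest = np.argmin(d, axis=1)  # argmin takes first on ties; index is sorted
    return pd.Series(
        cent.index.to_numpy()[nearest], index=comp_new.active.index, name="state"
    )


def pc_gene_signature(
    pca: PCAResult,
    marker_genes: dict[str, frozenset[str]],
    component: str = "PC2",
    coordinate_threshold: float = 0.5,
) -> frozenset[str]:
    """Union of marker sets of states loading strongly on one component.

    States (active or supplementary) whose coordinate on ``component`` is at
    least ``coordinate_threshold`` contribute their marker genes.
    """
    coords = pd.concat(
        [pca.variable_coordinates, pca.supplementary_coordinates]
    )[component]
    chosen = coords[coords >= coordinate_threshold].index
    genes: set[str] = set()
    for state in chosen:
        genes |= set(marker_genes.get(state, ()))
    return frozenset(genes)
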