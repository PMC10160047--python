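"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its arguments and an integer seed:
calling it twice with identical inputs yields bit-identical outputs. The
generators plant recoverable structure — whole-chromosome gains/losses in
neoplastic nuclei, archetypal cell-state compositions, pairwise spatial
colocalization, and enrichment-dependent hazards — so that every downstream
analysis can be validated against known truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tissuestates._errors import InvalidArgumentError

logger = logging.getLogger(__name__)

#: The 12 non-neoplastic cell states.
NON_NEOPLASTIC_STATES: tuple[str, ...] = (
    "Ast1",
    "Ast2",
    "Ast3",
    "Endothelial",
    "mgTAM",
    "moTAM",
    "Myel1",
    "Neuron",
    "Oligodendrocyte",
    "OPC",
    "prTAM",
    "Tcell",
)

#: The 6 neoplastic (glioma) transcriptional states.
GLIOMA_STATES: tuple[str, ...] = (
    "gl_PN1",
    "gl_PN2",
    "gl_Mes1",
    "gl_Mes2",
    "gl_Pro1",
    "gl_Pro2",
)

#: All 18 cell states, non-neoplastic first.
ALL_STATES: tuple[str, ...] = NON_NEOPLASTIC_STATES + GLIOMA_STATES

CONDITIONS = ("primary", "recurrent", "epilepsy", "LGG")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene panel with chromosome assignments.

    Genes carry a strictly increasing ``position_index`` within each
    chromosome, defining the genomic order used by windowed smoothing.
    """

    gene_ids: np.ndarray
    chromosomes: np.ndarray
    position_index: np.ndarray

    def __post_init__(self):
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise InvalidArgumentError("gene_ids must be unique")
        if len(np.unique(self.chromosomes)) < 2:
            raise InvalidArgumentError("panel must span at least 2 chromosomes")
        for chrom in np.unique(self.chromosomes):
            pos = self.position_index[self.chromosomes == chrom]
            if not np.all(np.diff(pos) > 0):
                raise InvalidArgumentError(
                    f"position_index not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def chromosome_order(self) -> list[str]:
        """Chromosome labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return list(seen)

    def genes_on(self, chromosome: str) -> np.ndarray:
        """Gene ids on ``chromosome`` in genomic order."""
        mask = self.chromosomes == chromosome
        order = np.argsort(self.position_index[mask], kind="stable")
        return self.gene_ids[mask][order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "chromosome": self.chromosomes,
                "position_index": self.position_index,
            }
        )


@dataclass(frozen=True)
class StateProfile:
    """Mean expression profile and marker genes for one cell state."""

    state_name: str
    mean_expression: np.ndarray
    marker_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if np.any(self.mean_expression < 0):
            raise InvalidArgumentError(
                f"mean_expression of {self.state_name} has negative entries"
            )


@dataclass(frozen=True)
class CNVProfile:
    """Planted whole-chromosome copy-number aberrations."""

    gained: frozenset[str]
    lost: frozenset[str]
    gain_factor: float = 1.5
    loss_factor: float = 0.5

    def __post_init__(self):
        if self.gained & self.lost:
            raise InvalidArgumentError("gained and lost chromosomes overlap")
        if not self.gain_factor > 1:
            raise InvalidArgumentError("gain_factor must exceed 1")
        if not 0 < self.loss_factor < 1:
            raise InvalidArgumentError("loss_factor must lie in (0, 1)")


@dataclass
class AnnotatedCountMatrix:
    """Gene x nucleus counts with per-nucleus annotations and QC fields."""

    counts: np.ndarray  # genes x nuclei, integer
    gene_ids: np.ndarray
    nucleus_meta: pd.DataFrame  # sample_id, condition, true_state, true_cnv_label
    qc: pd.DataFrame  # n_genes, total_reads, mito_fraction

    def __post_init__(self):
        if self.counts.shape[1] != len(self.nucleus_meta):
            raise InvalidArgumentError(
                "column count does not match metadata rows"
            )
        if self.counts.shape[0] != len(self.gene_ids):
            raise InvalidArgumentError("row count does not match gene_ids")
        if np.any(self.counts < 0) or not np.issubdtype(
            self.counts.dtype, np.integer
        ):
            raise InvalidArgumentError("counts must be nonnegative integers")

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    @property
    def nucleus_ids(self) -> np.ndarray:
        return self.nucleus_meta.index.to_numpy()

    def subset(self, mask: np.ndarray) -> "AnnotatedCountMatrix":
        """Return a copy restricted to nuclei where ``mask`` is True."""
        return AnnotatedCountMatrix(
            counts=self.counts[:, mask].copy(),
            gene_ids=self.gene_ids,
            nucleus_meta=self.nucleus_meta.loc[mask].copy(),
            qc=self.qc.loc[mask].copy(),
        )


@dataclass(frozen=True)
class SampleSpec:
    """Specification of one simulated snRNA-seq sample."""

    sample_id: str
    condition: str
    composition: dict[str, float]  # over the 18 states, sums to 1
    n_nuclei: int


@dataclass
class SpatialDataset:
    """Hex-lattice spot positions with per-spot cell-type proportions."""

    positions: pd.DataFrame  # spot_id index; row, col, x_um, y_um
    proportions: pd.DataFrame  # spot_id index x cell types
    sample_id: str = "sample"

    def __post_init__(self):
        if not self.positions.index.equals(self.proportions.index):
            raise InvalidArgumentError("positions/proportions index mismatch")
        sums = self.proportions.to_numpy().sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise InvalidArgumentError("proportion rows must sum to 1")

    @property
    def n_spots(self) -> int:
        return len(self.positions)

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class SurvivalTable:
    """Right-censored survival data with per-subject covariates."""

    data: pd.DataFrame  # time, event, plus covariate columns

    def __post_init__(self):
        if np.any(self.data["time"].to_numpy() <= 0):
            raise InvalidArgumentError("survival times must be positive")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise InvalidArgumentError("event must be 0/1")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_gene_panel(n_genes: int, n_chromosomes: int, seed: int = 0) -> GenePanel:
    """Build a gene panel with genes spread round-robin over chromosomes.

    Chromosomes are labelled ``"1" .. str(n_chromosomes)`` (a 23rd, if
    requested, is labelled ``"X"``). Deterministic for a fixed seed; the seed
    only shuffles nothing at present but is kept in the signature so future
    randomized layouts stay reproducible.
    """
    if n_chromosomes < 2:
        raise InvalidArgumentError("need at least 2 chromosomes")
    if n_chromosomes > n_genes:
        raise InvalidArgumentError(
            f"n_chromosomes ({n_chromosomes}) exceeds n_genes ({n_genes})"
        )
    labels = [str(i + 1) for i in range(min(n_chromosomes, 22))]
    if n_chromosomes == 23:
        labels.append("X")
    elif n_chromosomes > 23:
        raise InvalidArgumentError("at most 23 chromosomes (1..22, X)")
    chroms = np.array([labels[i % n_chromosomes] for i in range(n_genes)])
    pos = np.zeros(n_genes, dtype=int)
    counter: dict[str, int] = {}
    for i, c in enumerate(chroms):
        pos[i] = counter.get(c, 0)
        counter[c] = pos[i] + 1
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    order = np.lexsort((pos, np.array([labels.index(c) for c in chroms])))
    return GenePanel(
        gene_ids=gene_ids[order],
        chromosomes=chroms[order],
        position_index=pos[order],
    )


def make_state_profiles(
    panel: GenePanel,
    n_markers: int = 25,
    marker_fold: float = 8.0,
    state_sigma: float = 0.10,
    seed: int = 0,
) -> dict[str, StateProfile]:
    """Create 18 state profiles with disjoint marker-gene sets.

    All states share a lognormal baseline; each state multiplies it by a
    mild gene-wise lognormal perturbation (``state_sigma``) and elevates its
    ``n_markers`` dedicated marker genes ``marker_fold``-fold. Marker sets
    are disjoint and spread evenly across the panel so that neither markers
    nor state-specific baseline shifts masquerade as chromosome-scale
    copy-number signal.
    """
    if 18 * n_markers > panel.n_genes:
        raise InvalidArgumentError(
            "panel too small for disjoint marker blocks of this size"
        )
    rng = np.random.default_rng(seed)
    shared = rng.lognormal(mean=0.0, sigma=0.5, size=panel.n_genes)
    slots = np.round(
        np.linspace(0, panel.n_genes - 1, 18 * n_markers)
    ).astype(int)
    if len(np.unique(slots)) != len(slots):  # rounding collision on tiny panels
        slots = np.arange(18 * n_markers)
    profiles: dict[str, StateProfile] = {}
    for i, state in enumerate(ALL_STATES):
        base = shared * rng.lognormal(
            mean=0.0, sigma=state_sigma, size=panel.n_genes
        )
        block = slots[i::18]
        base[block] *= marker_fold
        markers = frozenset(panel.gene_ids[block])
        profiles[state] = StateProfile(
            state_name=state, mean_expression=base, marker_genes=markers
        )
    return profiles


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Draw NB counts with Var = mu + mu^2/theta (gamma-Poisson mixture)."""
    if not np.isfinite(theta) or theta <= 0:
        raise InvalidArgumentError("dispersion theta must be positive finite")
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def simulate_snrnaseq(
    panel: GenePanel,
    state_profiles: dict[str, StateProfile],
    sample_specs: list[SampleSpec],
    cnv_profile: CNVProfile,
    nb_dispersion: float = 10.0,
    library_size: float = 20000.0,
    library_sigma: float = 0.25,
    mito_beta: tuple[float, float] = (2.0, 38.0),
    seed: int = 0,
) -> AnnotatedCountMatrix:
    """Simulate an annotated snRNA-seq count matrix with planted CNVs.

    For each nucleus, a cell state is drawn from its sample's composition;
    gene means are the state's normalized expression profile scaled by a
    lognormal per-nucleus library size. Nuclei in glioma states additionally
    multiply genes on gained/lost chromosomes by the CNV factors and are
    labelled CNVpos; all others are CNVneg. Counts are negative-binomial
    with ``Var = mu + mu^2 / nb_dispersion``.
    """
    rng = np.random.default_rng(seed)
    glioma = set(GLIOMA_STATES)
    chrom_of = dict(zip(panel.gene_ids, panel.chromosomes))
    gain_mask = np.array([chrom_of[g] in cnv_profile.gained for g in panel.gene_ids])
    loss_mask = np.array([chrom_of[g] in cnv_profile.lost for g in panel.gene_ids])

    norm_profiles = {}
    for name, prof in state_profiles.items():
        if len(prof.mean_expression) != panel.n_genes:
            raise InvalidArgumentError(
                f"profile {name} length does not match panel"
            )
        norm_profiles[name] = prof.mean_expression / prof.mean_expression.sum()

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for spec in sample_specs:
        if spec.n_nuclei < 1:
            raise InvalidArgumentError("n_nuclei must be >= 1")
        states = list(spec.composition)
        probs = np.array([spec.composition[s] for s in states], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"composition of {spec.sample_id} sums to {probs.sum():.6g}, not 1"
            )
        unknown = [s for s in states if s not in norm_profiles]
        if unknown:
            raise InvalidArgumentError(f"unknown states in composition: {unknown}")
        drawn = rng.choice(len(states), size=spec.n_nuclei, p=probs)
        lib = library_size * rng.lognormal(
            mean=-0.5 * library_sigma**2, sigma=library_sigma, size=spec.n_nuclei
        )
        sample_counts = np.zeros((panel.n_genes, spec.n_nuclei), dtype=np.int64)
        for si, state in enumerate(states):
            cols = np.flatnonzero(drawn == si)
            if cols.size == 0:
                continue
            mu = norm_profiles[state][:, None] * lib[cols][None, :]
            if state in glioma:
                mu = mu.copy()
                mu[gain_mask, :] *= cnv_profile.gain_factor
                mu[loss_mask, :] *= cnv_profile.loss_factor
            sample_counts[:, cols] = _nb_sample(rng, mu, nb_dispersion)
        blocks.append(sample_counts)
        for i in range(spec.n_nuclei):
            state = states[drawn[i]]
            meta_rows.append(
                {
                    "nucleus_id": f"{spec.sample_id}:n{i:05d}",
                    "sample_id": spec.sample_id,
                    "condition": spec.condition,
                    "true_state": state,
                    "true_cnv_label": "CNVpos" if state in glioma else "CNVneg",
                }
            )

    counts = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("nucleus_id")
    total = counts.sum(axis=0)
    qc = pd.DataFrame(
        {
            "n_genes": (counts > 0).sum(axis=0),
            "total_reads": total,
            "mito_fraction": rng.beta(*mito_beta, size=counts.shape[1]),
        },
        index=meta.index,
    )
    return AnnotatedCountMatrix(
        counts=counts, gene_ids=panel.gene_ids.copy(), nucleus_meta=meta, qc=qc
    )


def qc_filter(
    matrix: AnnotatedCountMatrix,
    min_genes: int = 400,
    min_reads: int = 10000,
    max_mito: float = 0.15,
) -> AnnotatedCountMatrix:
    """Keep nuclei with enough detected genes and reads, and low mito load.

    Thresholds default to >=400 detected genes, >=10,000 reads and
    mitochondrial fraction <= 0.15. Per-criterion removal counts are logged.
    """
    qc = matrix.qc
    pass_genes = qc["n_genes"].to_numpy() >= min_genes
    pass_reads = qc["total_reads"].to_numpy() >= min_reads
    pass_mito = qc["mito_fraction"].to_numpy() <= max_mito
    keep = pass_genes & pass_reads & pass_mito
    logger.info(
        "qc_filter removed %d/%d nuclei (genes<%d: %d, reads<%d: %d, mito>%g: %d)",
        int((~keep).sum()),
        len(keep),
        min_genes,
        int((~pass_genes).sum()),
        min_reads,
        int((~pass_reads).sum()),
        max_mito,
        int((~pass_mito).sum()),
    )
    if not keep.any():
        warnings.warn("qc_filter removed every nucleus", stacklevel=2)
    return matrix.subset(keep)


def hex_lattice(
    lattice_rows: int, lattice_cols: int, pitch_um: float = 100.0
) -> pd.DataFrame:
    """Odd-row-offset hexagonal lattice positions.

    Rows are spaced ``pitch * sqrt(3)/2`` apart and odd rows are shifted by
    half a pitch, so first-order neighbors sit at center-to-center distance
    ``pitch_um`` (Visium-style packing).
    """
    if lattice_rows < 2 or lattice_cols < 2:
        raise InvalidArgumentError("lattice must be at least 2 x 2")
    rows, cols = np.meshgrid(
        np.arange(lattice_rows), np.arange(lattice_cols), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    x = (cols + 0.5 * (rows % 2)) * pitch_um
    y = rows * pitch_um * np.sqrt(3) / 2
    spot_ids = [f"spot_{r:03d}_{c:03d}" for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {"row": rows, "col": cols, "x_um": x, "y_um": y},
        index=pd.Index(spot_ids, name="spot_id"),
    )


def _smooth_field(
    rng: np.random.Generator, smoother: np.ndarray
) -> np.ndarray:
    z = rng.standard_normal(smoother.shape[0])
    f = smoother @ z
    return (f - f.mean()) / (f.std() + 1e-12)


def simulate_spatial(
    cell_types: list[str],
    lattice_rows: int,
    lattice_cols: int,
    pitch_um: float = 100.0,
    colocalization_spec: list[tuple[str, str, float]] = (),
    field_length_scale_um: float = 300.0,
    softmax_scale: float = 1.0,
    sample_id: str = "sample",
    seed: int = 0,
) -> SpatialDataset:
    """Simulate hex-lattice spot proportions with planted colocalization.

    Each cell type gets a smooth Gaussian-kernel random field; pairs listed
    in ``colocalization_spec`` mix in a shared latent field with the given
    weight, making their proportions positively cross-correlated in space.
    Per-spot proportions are a softmax over the latent fields.
    """
    positions = hex_lattice(lattice_rows, lattice_cols, pitch_um)
    for a, b, w in colocalization_spec:
        for t in (a, b):
            if t not in cell_types:
                raise InvalidArgumentError(f"unknown cell type in spec: {t}")
        if not 0 <= w <= 1:
            raise InvalidArgumentError("colocalization weight must be in [0, 1]")

    rng = np.random.default_rng(seed)
    xy = positions[["x_um", "y_um"]].to_numpy()
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2 * field_length_scale_um**2))
    smoother = kernel / kernel.sum(axis=1, keepdims=True)

    latent = {t: _smooth_field(rng, smoother) for t in cell_types}
    for a, b, w in colocalization_spec:
        shared = _smooth_field(rng, smoother)
        for t in (a, b):
            latent[t] = np.sqrt(1 - w**2) * latent[t] + w * shared

    z = softmax_scale * np.column_stack([latent[t] for t in cell_types])
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    props = ez / ez.sum(axis=1, keepdims=True)
    proportions = pd.DataFrame(props, index=positions.index, columns=cell_types)
    return SpatialDataset(
        positions=positions, proportions=proportions, sample_id=sample_id
    )


def simulate_bulk(
    state_profiles: dict[str, StateProfile],
    compositions: pd.DataFrame,
    library_size: float = 1e6,
    noise_dispersion: float = 10.0,
    gene_ids: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate bulk mixtures of state expression profiles.

    ``compositions`` is sample x state with rows summing to 1. Each sample's
    expected expression is the convex combination of normalized state
    profiles scaled to ``library_size``; counts are NB-sampled unless
    ``noise_dispersion`` is 0, in which case the exact expectation matrix is
    returned (no sampling). Pass ``gene_ids`` (e.g. ``panel.gene_ids``) when
    the profiles were built on a panel, so that rows are labelled
    consistently with it; the default is positional labels.
    """
    states = list(compositions.columns)
    unknown = [s for s in states if s not in state_profiles]
    if unknown:
        raise InvalidArgumentError(f"unknown states in compositions: {unknown}")
    fracs = compositions.to_numpy(dtype=float)
    if np.any(np.abs(fracs.sum(axis=1) - 1.0) > 1e-9):
        raise InvalidArgumentError("composition rows must sum to 1")
    profs = np.column_stack(
        [
            state_profiles[s].mean_expression
            / state_profiles[s].mean_expression.sum()
            for s in states
        ]
    )  # genes x states
    mean = library_size * profs @ fracs.T  # genes x samples
    n_genes = profs.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise InvalidArgumentError("gene_ids length must match profile length")
    if noise_dispersion == 0:
        data = mean
    else:
        rng = np.random.default_rng(seed)
        data = _nb_sample(rng, mean, noise_dispersion)
    return pd.DataFrame(data, index=gene_ids, columns=compositions.index)


def simulate_survival(
    enrichment: np.ndarray,
    log_hr: float = 0.0,
    baseline_scale: float = 365.0,
    censor_rate: float = 0.2,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
) -> SurvivalTable:
    """Simulate exponential survival with hazard driven by enrichment.

    Hazard of subject *i* is ``exp(log_hr * enrichment_i) / baseline_scale``.
    Censoring is independent: each subject is censored with probability
    ``censor_rate`` at a uniform time within their latent event time.
    """
    if not 0 <= censor_rate < 1:
        raise InvalidArgumentError("censor_rate must be in [0, 1)")
    enrichment = np.asarray(enrichment, dtype=float)
    rng = np.random.default_rng(seed)
    hazard = np.exp(log_hr * enrichment) / baseline_scale
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=len(enrichment)) < censor_rate
    time = np.where(censored, rng.uniform(size=len(enrichment)) * t_event, t_event)
    time = np.maximum(time, 1e-9)
    data = pd.DataFrame(
        {
            "time": time,
            "event": (~censored).astype(int),
            "enrichment": enrichment,
        }
    )
    if covariates is not None:
        data = pd.concat([data, covariates.reset_index(drop=True)], axis=1)
    return SurvivalTable(data=data)


def archetype_compositions(
    n_samples_per_archetype: int,
    concentration: float = 150.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-sample 18-state compositions around three archetypes.

    Archetypes mimic brain-like (neuron/oligodendrocyte-rich), reactive
    (astrocyte/myeloid-rich) and tumor-rich mixtures. Samples are Dirichlet
    draws around each archetype mean with the given concentration. Returns
    the composition table and the planted archetype label per sample.
    """
    base = np.full(18, 0.3)
    arch = {
        "brain": base.copy(),
        "reactive": base.copy(),
        "tumor": base.copy(),
    }
    idx = {s: i for i, s in enumerate(ALL_STATES)}
    for s, w in [("Neuron", 8.0), ("Oligodendrocyte", 6.0), ("Ast1", 2.0)]:
        arch["brain"][idx[s]] = w
    for s, w in [("Ast3", 6.0), ("moTAM", 5.0), ("mgTAM", 3.0), ("Myel1", 2.0)]:
        arch["reactive"][idx[s]] = w
    for s, w in [
        ("gl_PN1", 3.0),
        ("gl_Mes1", 3.0),
        ("gl_Pro1", 3.0),
        ("gl_Pro2", 2.0),
        ("gl_Mes2", 2.0),
        ("gl_PN2", 2.0),
    ]:
        arch["tumor"][idx[s]] = w

    rng = np.random.default_rng(seed)
    rows, labels, names = [], [], []
    for name, alpha_dir in arch.items():
        alpha = concentration * alpha_dir / alpha_dir.sum()
        for i in range(n_samples_per_archetype):
            rows.append(rng.dirichlet(alpha))
            labels.append(name)
            names.append(f"{name}_{i:02d}")
    comp = pd.DataFrame(rows, index=names, columns=list(ALL_STATES))
    return comp, pd.Series(labels, index=names, name="archetype")
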