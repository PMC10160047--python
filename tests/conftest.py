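import numpy as np
import pandas as pd
import pytest

from tissuestates import cnv, synthetic


@pytest.fixture(scope="session")
def panel2000():
    return synthetic.make_gene_panel(2000, 22, seed=1)


@pytest.fixture(scope="session")
def profiles2000(panel2000):
    return synthetic.make_state_profiles(panel2000, n_markers=25, seed=1)


@pytest.fixture(scope="session")
def cnv_710():
    return synthetic.CNVProfile(
        gained=frozenset({"7"}), lost=frozenset({"10"}),
        gain_factor=1.5, loss_factor=0.5,
    )


def planted_sample_specs(fractions, n_nuclei):
    """Sample specs with the given neoplastic fractions."""
    specs = []
    for i, f in enumerate(fractions):
        comp = {
            "gl_PN1": f / 3, "gl_Mes1": f / 3, "gl_Pro1": f / 3,
            "Neuron": (1 - f) * 0.3, "Oligodendrocyte": (1 - f) * 0.3,
            "Ast1": (1 - f) * 0.2, "mgTAM": (1 - f) * 0.2,
        }
        total = sum(comp.values())
        comp = {k: v / total for k, v in comp.items()}
        specs.append(
            synthetic.SampleSpec(f"sample{i + 1}", "primary", comp, n_nuclei)
        )
    return specs


@pytest.fixture(scope="session")
def snrna_planted(panel2000, profiles2000, cnv_710):
    """4 samples x 500 nuclei with planted chr7 gain / chr10 loss."""
    return synthetic.simulate_snrnaseq(
        panel2000,
        profiles2000,
        planted_sample_specs([0.3, 0.45, 0.55, 0.7], 500),
        cnv_710,
        nb_dispersion=50.0,
        library_size=60000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_profile(snrna_planted, panel2000):
    return cnv.chromosome_profile(snrna_planted, panel2000)


def tiny_count_matrix(counts, gene_ids, sample_ids, qc=None, states=None):
    """Hand-assembled AnnotatedCountMatrix for unit tests."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[1]
    ids = [f"n{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": ["primary"] * n,
            "true_state": states if states is not None else ["Neuron"] * n,
            "true_cnv_label": ["CNVneg"] * n,
        },
        index=pd.Index(ids, name="nucleus_id"),
    )
    if qc is None:
        qc = pd.DataFrame(
            {
                "n_genes": (counts > 0).sum(axis=0),
                "total_reads": counts.sum(axis=0),
                "mito_fraction": np.zeros(n),
            },
            index=meta.index,
        )
    else:
        qc = pd.DataFrame(qc, index=meta.index)
    return synthetic.AnnotatedCountMatrix(
        counts=counts,
        gene_ids=np.asarray(gene_ids, dtype=object),
        nucleus_meta=meta,
        qc=qc,
    )
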