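import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tissuestates import signatures as sg
from tissuestates._errors import InvalidArgumentError
from tissuestates.signatures import (
    DEResult,
    PseudobulkMatrix,
    bh_adjust,
    derive_state_signatures,
    gsva_scores,
    nb_wald_de,
    preranked_gsea,
    pseudobulk,
    size_factors,
    ssgsea,
)

from .conftest import tiny_count_matrix


def nb_counts(rng, mean, theta):
    lam = rng.gamma(theta, mean / theta)
    return rng.poisson(lam)


def make_pb(y, states, batches=None):
    counts = pd.DataFrame(
        y,
        index=[f"g{i}" for i in range(y.shape[0])],
        columns=[f"s{j}" for j in range(y.shape[1])],
    )
    meta = pd.DataFrame({"state": states}, index=counts.columns)
    if batches is not None:
        meta["batch"] = batches
    return PseudobulkMatrix(counts=counts, sample_meta=meta)


class TestPseudobulk:
    def test_single_nucleus_per_sample_rounds(self):
        m = tiny_count_matrix(
            [[1, 4], [2, 0]], ["g1", "g2"], ["a", "b"]
        )
        normalized = np.array([[1.4, 3.6], [2.5, 0.0]])
        pb = pseudobulk(m, normalized)
        assert pb.counts.loc["g1", "a"] == 1
        assert pb.counts.loc["g1", "b"] == 4
        assert pb.counts.loc["g2", "a"] == 3  # 2.5 rounds half-up

    def test_half_up_rounding_of_sums(self):
        m = tiny_count_matrix([[1, 1]], ["g1"], ["a", "a"])
        pb = pseudobulk(m, np.array([[1.2, 1.3]]))
        assert pb.counts.loc["g1", "a"] == 3

    def test_within_sample_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random((5, 6))
        m = tiny_count_matrix(
            np.ones((5, 6), dtype=np.int64), [f"g{i}" for i in range(5)],
            ["a", "a", "a", "b", "b", "b"],
        )
        perm = [2, 0, 1, 5, 3, 4]  # permutes within each sample
        m2 = tiny_count_matrix(
            np.ones((5, 6), dtype=np.int64), [f"g{i}" for i in range(5)],
            ["a", "a", "a", "b", "b", "b"],
        )
        pd.testing.assert_frame_equal(
            pseudobulk(m, vals).counts, pseudobulk(m2, vals[:, perm]).counts
        )


class TestSizeFactors:
    def test_hand_example(self):
        pb = make_pb(np.array([[1, 2], [2, 4]]), ["A", "B"])
        sf = size_factors(pb)
        assert sf["s0"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s1"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_unit_factors(self):
        pb = make_pb(np.tile([[3], [7], [1]], (1, 4)), ["A"] * 4)
        np.testing.assert_allclose(size_factors(pb).to_numpy(), 1.0)

    def test_doubling_equivariance(self):
        # doubling a sample's counts doubles its factor relative to the other
        # samples (the absolute factor scales by 2^(1 - 1/n) because the
        # per-gene geometric means shift by 2^(1/n))
        rng = np.random.default_rng(1)
        y = rng.integers(1, 50, (20, 3))
        base = size_factors(make_pb(y, ["A"] * 3))
        y2 = y.copy()
        y2[:, 0] *= 2
        doubled = size_factors(make_pb(y2, ["A"] * 3))
        assert doubled["s0"] / doubled["s1"] == pytest.approx(
            2 * base["s0"] / base["s1"]
        )
        assert doubled["s0"] == pytest.approx(2 ** (1 - 1 / 3) * base["s0"])

    def test_no_common_gene_rejected(self):
        pb = make_pb(np.array([[1, 0], [0, 1]]), ["A", "B"])
        with pytest.raises(InvalidArgumentError, match="pseudocount"):
            size_factors(pb)


class TestNbWaldDe:
    def test_flat_gene_null(self):
        # identical counts across samples (unit size factors): no evidence
        rng = np.random.default_rng(0)
        col = rng.integers(10, 100, size=200)
        y = np.tile(col[:, None], (1, 8))
        pb = make_pb(y, ["A"] * 4 + ["B"] * 4)
        res = nb_wald_de(pb, pb.sample_meta["state"], None, ("A", "B"))
        assert res.table["log2_fold_change"].abs().max() == pytest.approx(
            0, abs=1e-6
        )
        assert res.table["p_value"].min() > 0.9

    def test_type_one_error_calibrated(self):
        # null simulation: no state effect, theta = 10, 6 vs 6, 2000 genes
        rng = np.random.default_rng(42)
        rates = []
        for rep in range(10):
            mu = rng.lognormal(3, 1, 2000)
            sf_true = rng.lognormal(0, 0.2, 12)
            y = nb_counts(rng, mu[:, None] * sf_true[None, :], 10.0)
            pb = make_pb(y, ["A"] * 6 + ["B"] * 6, ["b1", "b2"] * 6)
            res = nb_wald_de(
                pb, pb.sample_meta["state"], pb.sample_meta["batch"], ("A", "B")
            )
            rates.append((res.table["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_power_on_planted_fold_changes(self):
        rng = np.random.default_rng(7)
        G = 2000
        mu = rng.lognormal(3, 1, G)
        fc = np.ones(G)
        de_idx = rng.choice(G, 100, replace=False)
        fc[de_idx] = 4.0
        mean = np.tile(mu[:, None], (1, 12))
        mean[:, 6:] *= fc[:, None]
        y = nb_counts(rng, mean, 10.0)
        pb = make_pb(y, ["A"] * 6 + ["B"] * 6)
        res = nb_wald_de(pb, pb.sample_meta["state"], None, ("B", "A"))
        sig = res.table["q_value"] < 0.05
        assert sig.iloc[de_idx].mean() >= 0.8

    def test_confounded_batch_rejected(self):
        rng = np.random.default_rng(3)
        y = nb_counts(rng, np.full((50, 8), 30.0), 10.0)
        pb = make_pb(y, ["A"] * 4 + ["B"] * 4, ["b1"] * 4 + ["b2"] * 4)
        with pytest.raises(InvalidArgumentError, match="confounded"):
            nb_wald_de(
                pb, pb.sample_meta["state"], pb.sample_meta["batch"], ("A", "B")
            )

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(4)
        y = nb_counts(rng, np.full((10, 3), 30.0), 10.0)
        pb = make_pb(y, ["A", "A", "B"])
        with pytest.raises(InvalidArgumentError):
            nb_wald_de(pb, pb.sample_meta["state"], None, ("A", "B"))


def bh_bruteforce(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_bruteforce(self, p):
        np.testing.assert_allclose(
            bh_adjust(p), bh_bruteforce(np.asarray(p)), atol=1e-12
        )

    def test_matches_bruteforce_long_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            p = rng.random(1000)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


def de_from_table(genes, lfc, q, contrast):
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "wald_statistic": np.zeros(len(genes)),
            "p_value": q,
            "q_value": q,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(
        table=table,
        contrast=contrast,
        size_factors=pd.Series(dtype=float),
        dispersions=pd.Series(dtype=float),
    )


class TestDeriveStateSignatures:
    def test_candidate_set_logic(self):
        # g1, g2 up in B vs A and B vs C; g3 up in C only; nothing for A.
        # (A gene cannot be up in both B-vs-C and C-vs-B, so with one DE
        # table per pair the per-state candidate sets are disjoint by
        # construction; the uniqueness filter is a defensive no-op here.)
        genes = ["g1", "g2", "g3"]
        de_ab = de_from_table(genes, [-2.0, -3.0, 0.0], [0.01, 0.01, 0.9], ("A", "B"))
        de_ac = de_from_table(genes, [0.0, 0.0, -2.0], [0.9, 0.9, 0.01], ("A", "C"))
        de_bc = de_from_table(genes, [2.0, 3.0, -2.0], [0.01, 0.01, 0.01], ("B", "C"))
        sigs = derive_state_signatures(de_ab, de_ac, de_bc)
        assert set(sigs["B"].genes) == {"g1", "g2"}
        assert sigs["B"].genes[0] == "g2"  # higher mean lfc ranks first
        assert set(sigs["C"].genes) == {"g3"}
        assert sigs["A"].genes == ()
        # pairwise disjoint
        assert not set(sigs["B"].genes) & set(sigs["C"].genes)

    def test_no_significant_genes_empty(self):
        genes = ["g1", "g2"]
        de_ab = de_from_table(genes, [1.0, -1.0], [0.5, 0.5], ("A", "B"))
        de_ac = de_from_table(genes, [1.0, -1.0], [0.5, 0.5], ("A", "C"))
        de_bc = de_from_table(genes, [1.0, -1.0], [0.5, 0.5], ("B", "C"))
        with pytest.warns(UserWarning, match="empty signature"):
            sigs = derive_state_signatures(de_ab, de_ac, de_bc)
        assert all(len(s.genes) == 0 for s in sigs.values())

    def test_truncation_to_top_n(self):
        genes = [f"g{i}" for i in range(300)]
        lfc_up = np.linspace(3, 1, 300)
        de_ab = de_from_table(genes, lfc_up, np.full(300, 0.001), ("A", "B"))
        de_ac = de_from_table(genes, lfc_up, np.full(300, 0.001), ("A", "C"))
        de_bc = de_from_table(genes, np.zeros(300), np.ones(300), ("B", "C"))
        sigs = derive_state_signatures(de_ab, de_ac, de_bc, top_n=150)
        assert len(sigs["A"].genes) == 150
        assert sigs["A"].genes[0] == "g0"  # highest mean lfc first


def ssgsea_oracle(values, genes, gene_set, tau):
    """Direct enumeration of the weighted running-sum score for one sample."""
    order = sorted(range(len(genes)), key=lambda i: (-values[i], i))
    n = len(genes)
    in_set = [genes[i] in gene_set for i in order]
    weights = [(n - pos) ** tau if in_set[pos] else 0.0 for pos in range(n)]
    denom_in = sum(weights)
    n_out = n - sum(in_set)
    es = 0.0
    cum_in = cum_out = 0.0
    for pos in range(n):
        cum_in += weights[pos] / denom_in
        cum_out += (0 if in_set[pos] else 1) / n_out
        es += cum_in - cum_out
    return es


class TestSsgsea:
    def test_constant_expression_identical_scores(self):
        expr = pd.DataFrame(
            np.tile([[5.0], [3.0], [1.0], [2.0]], (1, 4)),
            index=["g1", "g2", "g3", "g4"],
            columns=list("abcd"),
        )
        scores = ssgsea(expr, {"set1": ["g1", "g3"]}, normalize=False)
        assert scores["set1"].nunique() == 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.random((20, 3)), index=[f"g{i}" for i in range(20)],
            columns=list("abc"),
        )
        sets = {"s": ["g1", "g5", "g9"]}
        a = ssgsea(expr, sets, normalize=False)
        b = ssgsea(np.exp(expr * 3) + 7, sets, normalize=False)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_bruteforce_oracle_tau0(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        vals = [5.0, 4.0, 3.0, 2.0, 1.0]
        expr = pd.DataFrame({"s1": vals}, index=genes)
        score = ssgsea(expr, {"set": ["g1", "g3"]}, tau=0.0, normalize=False)
        expected = ssgsea_oracle(vals, genes, {"g1", "g3"}, 0.0)
        assert score.loc["s1", "set"] == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame(
            rng.random((10, 4)), index=genes, columns=list("abcd")
        )
        gene_set = {"g0", "g3", "g7"}
        scores = ssgsea(expr, {"s": sorted(gene_set)}, tau=0.25, normalize=False)
        for j, col in enumerate(expr.columns):
            expected = ssgsea_oracle(
                expr[col].to_numpy(), genes, gene_set, 0.25
            )
            assert scores.loc[col, "s"] == pytest.approx(expected, abs=1e-10)

    def test_range_normalization(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.random((30, 5)), index=[f"g{i}" for i in range(30)],
            columns=list("abcde"),
        )
        sets = {"a": ["g1", "g2"], "b": ["g5", "g6", "g7"]}
        scores = ssgsea(expr, sets, normalize=True)
        rng_ = scores.to_numpy().max() - scores.to_numpy().min()
        assert rng_ == pytest.approx(1.0)

    def test_missing_set_dropped_with_warning(self):
        expr = pd.DataFrame(
            [[1.0], [2.0]], index=["g1", "g2"], columns=["s"]
        )
        with pytest.warns(UserWarning, match="dropped"):
            scores = ssgsea(expr, {"ok": ["g1"], "gone": ["zz"]})
        assert list(scores.columns) == ["ok"]


def gsva_oracle(expr, gene_set, mx_diff):
    """Loop implementation of the kernel-CDF + symmetric-rank walk score."""
    genes = list(expr.index)
    x = expr.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    z = np.zeros_like(x)
    for g in range(n_genes):
        h = max(np.std(x[g], ddof=1) / 4, 1e-12)
        for j in range(n_samples):
            z[g, j] = np.mean(stats.norm.cdf((x[g, j] - x[g]) / h))
    out = []
    for j in range(n_samples):
        order = sorted(range(n_genes), key=lambda g: (-z[g, j], g))
        r = [abs(n_genes / 2 - (pos + 1)) for pos in range(n_genes)]
        hits = [genes[g] in gene_set for g in order]
        wsum = sum(r[pos] for pos in range(n_genes) if hits[pos])
        n_out = n_genes - sum(hits)
        nu, cum_in, cum_out = [], 0.0, 0.0
        for pos in range(n_genes):
            if hits[pos]:
                cum_in += r[pos] / wsum
            else:
                cum_out += 1 / n_out
            nu.append(cum_in - cum_out)
        if mx_diff:
            out.append(max(max(nu), 0) + min(min(nu), 0))
        else:
            out.append(nu[int(np.argmax(np.abs(nu)))])
    return np.array(out)


class TestGsva:
    def test_all_genes_set_scores_zero(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.random((6, 4)), index=[f"g{i}" for i in range(6)],
            columns=list("abcd"),
        )
        scores = gsva_scores(expr, {"all": list(expr.index)})
        np.testing.assert_allclose(scores["all"].to_numpy(), 0.0)

    def test_top_ranked_set_positive(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.random((12, 4)), index=[f"g{i}" for i in range(12)],
            columns=list("abcd"),
        )
        expr.loc[["g0", "g1", "g2"], "a"] += 10  # set genes top-ranked in a
        scores = gsva_scores(expr, {"s": ["g0", "g1", "g2"]})
        assert scores.loc["a", "s"] > 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.random((10, 4)), index=[f"g{i}" for i in range(10)],
            columns=list("abcd"),
        )
        gene_set = {"g1", "g4", "g8"}
        for mx_diff in (True, False):
            scores = gsva_scores(
                expr, {"s": sorted(gene_set)}, mx_diff=mx_diff
            )
            expected = gsva_oracle(expr, gene_set, mx_diff)
            np.testing.assert_allclose(
                scores["s"].to_numpy(), expected, atol=1e-10
            )

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["a", "b"]
        )
        with pytest.raises(InvalidArgumentError):
            gsva_scores(expr, {"s": ["g1"]})


class TestPrerankedGsea:
    def test_worked_example(self):
        metric = pd.Series(
            [3.0, 2.0, 1.0, -1.0, -2.0],
            index=["g1", "g2", "g3", "g4", "g5"],
        )
        res = preranked_gsea(metric, ["g1", "g3"], n_perm=100, seed=0)
        assert res.es == pytest.approx(0.75)

    def test_running_sum_values(self):
        # frozen hand computation of the full walk for the worked example
        from tissuestates.signatures import _running_es

        vals = np.array([3.0, 2.0, 1.0, -1.0, -2.0])
        hits = np.array([True, False, True, False, False])
        walk, es, _ = _running_es(vals, hits, 1.0)
        np.testing.assert_allclose(
            walk, [0.75, 0.75 - 1 / 3, 0.75 - 1 / 3 + 0.25, 1 / 3, 0.0],
            atol=1e-12,
        )
        assert es == pytest.approx(0.75)

    def test_full_universe_set_is_zero(self):
        metric = pd.Series([2.0, 1.0, -1.0], index=["g1", "g2", "g3"])
        res = preranked_gsea(metric, ["g1", "g2", "g3"], n_perm=10, seed=0)
        assert res.es == 0.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        metric = pd.Series(
            rng.standard_normal(50), index=[f"g{i}" for i in range(50)]
        )
        a = preranked_gsea(metric, [f"g{i}" for i in range(5)], seed=3)
        b = preranked_gsea(metric, [f"g{i}" for i in range(5)], seed=3)
        assert a.p_value == b.p_value
        assert a.nes == b.nes

    def test_empty_intersection_rejected(self):
        metric = pd.Series([1.0, 2.0], index=["g1", "g2"])
        with pytest.raises(InvalidArgumentError):
            preranked_gsea(metric, ["zz"], seed=0)

    def test_p_floor(self):
        rng = np.random.default_rng(5)
        metric = pd.Series(
            np.concatenate([np.full(10, 5.0), rng.standard_normal(200)]),
            index=[f"g{i}" for i in range(210)],
        )
        res = preranked_gsea(metric, [f"g{i}" for i in range(10)],
                             n_perm=200, seed=1)
        assert res.p_value >= 1 / 201
        assert res.nes > 1


class TestSignaturePipelineIntegration:
    """End-to-end: tissue states -> DE signatures -> enrichment on bulk."""

    def test_signature_scores_track_planted_composition(
        self, panel2000, profiles2000, cnv_710
    ):
        from tissuestates import composition as cp
        from tissuestates import synthetic

        rng = np.random.default_rng(0)
        comp18, labels = synthetic.archetype_compositions(3, seed=1)
        specs = [
            synthetic.SampleSpec(
                s, "primary", comp18.loc[s].to_dict(), 250
            )
            for s in comp18.index
        ]
        m = synthetic.simulate_snrnaseq(
            panel2000, profiles2000, specs, cnv_710,
            nb_dispersion=50.0, library_size=20000.0, seed=2,
        )
        ann = m.nucleus_meta.rename(
            columns={"true_state": "state", "true_cnv_label": "cnv_label"}
        )
        comp = cp.composition_matrix(ann.reset_index())
        assignment = cp.cluster_tissue_states(comp, k=3)

        pb = pseudobulk(m)
        pb.sample_meta["state"] = assignment.states.reindex(pb.counts.columns)
        de_ab = nb_wald_de(pb, pb.sample_meta["state"], None, ("A", "B"))
        de_ac = nb_wald_de(pb, pb.sample_meta["state"], None, ("A", "C"))
        de_bc = nb_wald_de(pb, pb.sample_meta["state"], None, ("B", "C"))
        sigs = derive_state_signatures(de_ab, de_ac, de_bc)
        assert all(len(s.genes) > 0 for s in sigs.values())

        # 30 bulk mixtures spanning the three archetypes
        bulk_comp, bulk_labels = synthetic.archetype_compositions(
            10, concentration=30.0, seed=3
        )
        bulk = synthetic.simulate_bulk(
            profiles2000, bulk_comp, library_size=2e5,
            noise_dispersion=10.0, gene_ids=panel2000.gene_ids, seed=4,
        )
        gene_sets = {st: list(sig.genes) for st, sig in sigs.items()}
        scores = ssgsea(np.log1p(bulk), gene_sets)

        planted = {
            "A": bulk_comp[["Neuron", "Oligodendrocyte"]].sum(axis=1),
            "B": bulk_comp[["Ast3", "moTAM", "mgTAM", "Myel1"]].sum(axis=1),
            "C": bulk_comp[
                [s for s in synthetic.GLIOMA_STATES]
            ].sum(axis=1),
        }
        for st in ("A", "B", "C"):
            rho, _ = stats.spearmanr(scores[st], planted[st])
            assert rho >= 0.7, f"state {st}: spearman {rho:.2f}"
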