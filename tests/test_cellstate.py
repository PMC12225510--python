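import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cimp_atlas import cellstate, cimp, synthetic
from cimp_atlas.cellstate import GeneSet
from cimp_atlas.core_io import BetaMatrix, CgiAnnotation
from cimp_atlas.synthetic import SimConfig


def _expr(n_genes=200, n_cells=50, seed=0, constant=None):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cells = [f"cell{i:02d}" for i in range(n_cells)]
    if constant is not None:
        values = np.full((n_genes, n_cells), float(constant))
    else:
        values = rng.lognormal(1.0, 0.8, size=(n_genes, n_cells))
    return pd.DataFrame(values, index=genes, columns=cells)


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        df = _expr(constant=3.0)
        gs = GeneSet("m", frozenset(["g001", "g002", "g003"]))
        score = cellstate.module_score(df, gs, seed=1)
        assert np.allclose(score, 0.0)

    def test_shifted_cells_score_higher(self):
        """Upshifting the set genes in half the cells raises exactly their score."""
        df = _expr(constant=3.0)
        set_genes = ["g000", "g001", "g002", "g003"]
        half = df.columns[:25]
        df.loc[set_genes, half] += 2.0
        gs = GeneSet("m", frozenset(set_genes))
        score = cellstate.module_score(df, gs, seed=2)
        assert score[half].mean() - score[df.columns[25:]].mean() == pytest.approx(2.0, abs=1e-9)
        assert score[df.columns[25:]].mean() == pytest.approx(0.0, abs=1e-9)

    def test_random_within_bin_sets_center_at_zero(self):
        df = _expr(n_genes=480, seed=3)
        avg = df.mean(axis=1).sort_values()
        one_bin = list(avg.index[100:120])  # genes of similar expression
        rng = np.random.default_rng(3)
        means = []
        for i in range(100):
            genes = rng.choice(one_bin, size=5, replace=False)
            gs = GeneSet(f"r{i}", frozenset(genes))
            means.append(cellstate.module_score(df, gs, seed=i).mean())
        assert abs(np.mean(means)) < 0.05

    def test_deterministic_under_seed(self):
        df = _expr(seed=4)
        gs = GeneSet("m", frozenset(["g000", "g010", "g020"]))
        s1 = cellstate.module_score(df, gs, seed=9)
        s2 = cellstate.module_score(df, gs, seed=9)
        pd.testing.assert_series_equal(s1, s2)

    def test_disjoint_set_errors(self):
        df = _expr()
        with pytest.raises(ValueError):
            cellstate.module_score(df, GeneSet("m", frozenset(["nope"])), seed=0)


class TestCimpExpressionScore:
    def _calls_and_annots(self, called_ids, gene_of):
        anns = {
            cid: CgiAnnotation(cid, "promoter", frozenset({gene_of[cid]}), 100)
            for cid in called_ids
        }
        return called_ids, anns

    def test_identical_target_sets_identical_scores(self):
        df = _expr(seed=5)
        gene_of = {"c1": "g001", "c2": "g002"}
        called, anns = self._calls_and_annots(["c1", "c2"], gene_of)
        s1 = cellstate.cimp_expression_score(df, called, anns, "RTK2", seed=3)
        s2 = cellstate.cimp_expression_score(df, called, anns, "IDH", seed=3)
        pd.testing.assert_series_equal(s1, s2, check_names=False)

    def test_no_calls_errors(self):
        df = _expr()
        with pytest.raises(ValueError, match="no CIMP CGIs"):
            cellstate.cimp_expression_score(df, [], {}, "RTK2")

    def test_no_promoter_targets_errors(self):
        df = _expr()
        anns = {"c1": CgiAnnotation("c1", "intergenic", frozenset(), 100)}
        with pytest.raises(ValueError, match="target genes"):
            cellstate.cimp_expression_score(df, ["c1"], anns, "RTK2")

    def test_state_contrast_recovered(self):
        """Cells of the state whose module genes are CIMP targets score higher."""
        cfg = SimConfig(n_cells_per_state=50, state_shift=1.5, seed=6)
        expr, truth = synthetic.simulate_single_cells(cfg)
        target_genes = truth.state_modules["NPC"]
        gs = GeneSet("targets", frozenset(target_genes))
        score = cellstate.module_score(np.log1p(expr.values), gs, seed=6)
        npc = score[truth.cell_states == "NPC"]
        other = score[truth.cell_states != "NPC"]
        _, p = stats.mannwhitneyu(npc, other, alternative="greater")
        assert p < 0.01


class TestScoreLog2fc:
    def test_simple_ratio(self):
        a = pd.Series([2.0], index=["c"])
        b = pd.Series([1.0], index=["c"])
        assert cellstate.score_log2fc(a, b, eps=1e-12)["c"] == pytest.approx(1.0)

    def test_negative_scores_clamped(self):
        a = pd.Series([-0.5], index=["c"])
        b = pd.Series([-0.5], index=["c"])
        assert cellstate.score_log2fc(a, b)["c"] == 0.0

    def test_equal_scores_zero(self):
        a = pd.Series([1.3, 0.2], index=["c1", "c2"])
        assert (cellstate.score_log2fc(a, a.copy()) == 0).all()


class TestMarkerTargeting:
    def _annotations(self):
        anns = {}
        for i in range(20):
            gene = f"g{i:02d}"
            anns[f"c{i}"] = CgiAnnotation(f"c{i}", "promoter", frozenset({gene}), 10)
        return anns

    def test_fraction_arithmetic(self):
        anns = self._annotations()
        called = [f"c{i}" for i in range(5)]  # targets g00..g04
        markers = GeneSet("set1", frozenset(f"g{i:02d}" for i in range(20)))
        out = cellstate.marker_target_fraction([markers], called, anns)
        assert out.loc[0, "pct_targeted"] == pytest.approx(25.0)

    def test_no_overlap_zero(self):
        anns = self._annotations()
        markers = GeneSet("set1", frozenset({"unrelated"}))
        out = cellstate.marker_target_fraction([markers], ["c0"], anns)
        assert out.loc[0, "pct_targeted"] == 0.0

    def test_empty_marker_list_errors(self):
        with pytest.raises(ValueError):
            cellstate.marker_target_fraction([], ["c0"], self._annotations())


class TestSelectMarkers:
    def _table(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "q": [0.005, 0.02, 0.01, 0.009],
                "lfc": [1.5, 3.0, 1.0, 2.0],
                "population": ["neuron_1", "neuron_2", "glia", "glia"],
            }
        )

    def test_filters_and_boundaries(self):
        kept = cellstate.select_markers(self._table())
        # a: kept; b: q too high; c: lfc not strictly > 1; d: kept
        assert list(kept["gene"]) == ["a", "d"]

    def test_label_collapse(self):
        kept = cellstate.select_markers(
            self._table(), label_map={"neuron_1": "neurons", "neuron_2": "neurons"}
        )
        assert set(kept["population"]) <= {"neurons", "glia"}

    def test_missing_column_errors(self):
        with pytest.raises(ValueError):
            cellstate.select_markers(self._table().drop(columns=["q"]))


class TestDeconvolve:
    def test_identity_reference_recovers_vector(self):
        ref = pd.DataFrame(np.eye(4), index=[f"m{i}" for i in range(4)],
                           columns=["AC", "MES", "NPC", "OPC"])
        bulk = pd.DataFrame({"s1": [0.6, 0.3, 0.1, 0.0]}, index=ref.index)
        out = cellstate.deconvolve(ref, bulk)
        assert np.allclose(out["proportions"].loc["s1"], [0.6, 0.3, 0.1, 0.0])

    def test_noiseless_mixture_exact(self):
        rng = np.random.default_rng(7)
        ref = pd.DataFrame(rng.uniform(0, 10, size=(50, 4)),
                           index=[f"g{i}" for i in range(50)],
                           columns=["AC", "MES", "NPC", "OPC"])
        props = np.array([0.5, 0.2, 0.2, 0.1])
        bulk = pd.DataFrame({"s1": ref.to_numpy() @ props}, index=ref.index)
        out = cellstate.deconvolve(ref, bulk)
        assert np.allclose(out["proportions"].loc["s1"], props, atol=1e-9)

    def test_nnls_variant_nonnegative(self):
        rng = np.random.default_rng(8)
        ref = pd.DataFrame(rng.uniform(0, 10, size=(50, 4)),
                           index=[f"g{i}" for i in range(50)], columns=list("ABCD"))
        bulk = pd.DataFrame(rng.uniform(0, 10, size=(50, 3)), index=ref.index,
                            columns=["s1", "s2", "s3"])
        out = cellstate.deconvolve(ref, bulk, method="nnls")
        assert (out["raw_coefficients"].to_numpy() >= 0).all()
        assert np.allclose(out["proportions"].sum(axis=1), 1.0)

    def test_rank_deficient_errors(self):
        ref = pd.DataFrame(np.ones((10, 3)), index=[f"g{i}" for i in range(10)],
                           columns=list("ABC"))
        bulk = pd.DataFrame(np.ones((10, 1)), index=ref.index, columns=["s1"])
        with pytest.raises(ValueError, match="rank"):
            cellstate.deconvolve(ref, bulk)


class TestPairedTargetExpression:
    def test_identical_strata_p_one(self):
        df = _expr(n_genes=20, n_cells=6, constant=2.0)
        markers = GeneSet("m", frozenset(df.index[:10]))
        flags = pd.Series([True] * 5 + [False] * 5, index=df.index[:10])
        out = cellstate.paired_target_expression(df, markers, flags)
        assert out["wilcoxon_p"] == 1.0

    def test_systematic_shift_detected(self):
        df = _expr(n_genes=40, n_cells=12, seed=9)
        targeted = list(df.index[:10])
        df.loc[targeted] *= 0.25  # silenced targets
        markers = GeneSet("m", frozenset(df.index[:20]))
        flags = pd.Series([g in targeted for g in df.index[:20]], index=df.index[:20])
        out = cellstate.paired_target_expression(df, markers, flags)
        assert (out["difference"] < 0).all()
        assert out["wilcoxon_p"] < 0.01

    def test_empty_stratum_errors(self):
        df = _expr(n_genes=10, n_cells=4)
        markers = GeneSet("m", frozenset(df.index[:4]))
        flags = pd.Series(True, index=df.index[:4])
        with pytest.raises(ValueError):
            cellstate.paired_target_expression(df, markers, flags)


class TestMethExprCorrelation:
    def _cohort(self, coupling, seed=10):
        cfg = SimConfig(n_cgi=80, n_planted_idh=10, n_planted_rtk2=10, seed=seed)
        beta, truth = synthetic.simulate_methylation_cohort(cfg)
        expr, truth = synthetic.simulate_expression(
            beta, truth, coupling=coupling, noise_sd=0.1, seed=seed
        )
        return beta, expr, truth

    def test_exact_negative_relationship(self):
        samples = [f"A_{i}" for i in range(6)] + [f"B_{i}" for i in range(6)]
        groups = {s: s.split("_")[0] for s in samples}
        rng = np.random.default_rng(11)
        b = pd.DataFrame(rng.uniform(size=(3, 12)), index=["c1", "c2", "c3"],
                         columns=samples)
        beta = BetaMatrix(b, groups)
        expr = 1.0 - b
        expr.index = ["g1", "g2", "g3"]
        cgi_map = pd.Series({"c1": "g1", "c2": "g2", "c3": "g3"})
        out = cellstate.meth_expr_correlation(beta, expr, cgi_map, "A", "B")
        assert np.allclose(out["rho_a"], -1.0)

    def test_coupled_group_more_negative(self):
        """Coupling planted in all samples: both groups strongly negative."""
        beta, expr, truth = self._cohort(coupling=2.0)
        out = cellstate.meth_expr_correlation(
            beta, expr, truth.cgi_gene_map, "RTK2", "MES"
        )
        assert out["rho_a"].mean() < -0.3

    def test_uncoupled_centered_at_zero(self):
        beta, expr, truth = self._cohort(coupling=0.0, seed=12)
        out = cellstate.meth_expr_correlation(
            beta, expr, truth.cgi_gene_map, "RTK2", "MES"
        )
        assert abs(out["rho_a"].mean()) < 0.1


class TestScMethylationFraction:
    def test_simple_ratio(self):
        calls = pd.DataFrame(
            {"cell": ["a"] * 4, "cgi_id": ["c1"] * 4, "cpg_index": range(4),
             "methylated": [1, 1, 1, 0]}
        )
        out = cellstate.sc_methylation_fraction(calls, ["c1"], {"a": "AC"})
        assert out.loc["AC", "c1"] == pytest.approx(0.75)

    def test_literal_ratio_variant(self):
        calls = pd.DataFrame(
            {"cell": ["a"] * 4, "cgi_id": ["c1"] * 4, "cpg_index": range(4),
             "methylated": [1, 1, 1, 0]}
        )
        out = cellstate.sc_methylation_fraction(calls, ["c1"], {"a": "AC"}, as_ratio=True)
        assert out.loc["AC", "c1"] == pytest.approx(3.0)

    def test_zero_coverage_missing(self):
        calls = pd.DataFrame(
            {"cell": ["a"], "cgi_id": ["c1"], "cpg_index": [0], "methylated": [1]}
        )
        out = cellstate.sc_methylation_fraction(calls, ["c1", "c2"], {"a": "AC"})
        assert np.isnan(out.loc["AC", "c2"])

    def test_pooled_estimate_concentrates(self):
        fracs = pd.Series({"c1": 0.7})
        calls = synthetic.simulate_sparse_cpg_calls(
            fracs, n_cpg_per_cgi=100, n_cells=300, coverage=0.1, seed=13
        )
        out = cellstate.sc_methylation_fraction(calls, ["c1"])
        assert abs(out.loc["all", "c1"] - 0.7) < 0.05

    def test_empty_region_set_errors(self):
        with pytest.raises(ValueError):
            cellstate.sc_methylation_fraction(pd.DataFrame(), [])


class TestEndToEndPlantedPipeline:
    """Planted methylation -> coupled expression -> CIMP calls -> targeting."""

    def test_planted_silencing_detected_through_calls(self):
        cfg = SimConfig(n_cgi=400, n_planted_idh=30, n_planted_rtk2=30, seed=14)
        beta, truth = synthetic.simulate_methylation_cohort(cfg)
        expr, truth = synthetic.simulate_expression(beta, truth, coupling=2.0, seed=14)
        calls = cimp.call_cimp(beta, "RTK2", ["MES", "RTK1"])
        called = set(calls.called_ids)
        planted = set(truth.cimp_labels.index[truth.cimp_labels == "RTK2-CIMP"])
        assert len(called & planted) / len(planted) > 0.9
        # target genes of called CGIs are lower-expressed in RTK2 than MES
        rtk2 = beta.samples_in_group("RTK2")
        mes = beta.samples_in_group("MES")
        genes = truth.cgi_gene_map[list(called & planted)]
        log_expr = np.log1p(expr.values)
        diff = log_expr.loc[genes, rtk2].mean(axis=1) - log_expr.loc[genes, mes].mean(axis=1)
        assert (diff < 0).mean() >= 0.95
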