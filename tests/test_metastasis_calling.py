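import numpy as np
import pandas as pd
import pytest

import metscreen as ms

from conftest import make_gene_result


def comparison_set(lung=None, liver=None, pref=None, cell_line="X"):
    return ms.MouseComparisonSet(cell_line=cell_line, lung=lung or {},
                                 liver=liver or {},
                                 lung_preference=pref or {})


class TestSelectMice:
    def test_picks_highest_lung_preference(self):
        pref = {"m1": 0.9, "m2": 0.8, "m3": 0.7, "m4": 0.6, "m5": 0.2}
        lung = {m: make_gene_result({"A": {}}) for m in pref}
        cs = comparison_set(lung=lung, pref=pref)
        assert ms.select_mice(cs, 4) == ["m1", "m2", "m3", "m4"]

    def test_equal_preferences_break_ties_by_id(self):
        lung = {m: make_gene_result({"A": {}}) for m in ("m3", "m1", "m2")}
        cs = comparison_set(lung=lung, pref={m: 0.5 for m in lung})
        assert ms.select_mice(cs, 2) == ["m1", "m2"]

    def test_k_equal_to_available_is_identity(self):
        lung = {m: make_gene_result({"A": {}}) for m in ("m1", "m2")}
        cs = comparison_set(lung=lung, pref={"m1": 0.2, "m2": 0.9})
        assert sorted(ms.select_mice(cs, 2)) == ["m1", "m2"]

    def test_too_few_mice_warns_and_uses_all(self, caplog):
        lung = {"m1": make_gene_result({"A": {}})}
        cs = comparison_set(lung=lung, pref={"m1": 1.0})
        with caplog.at_level("WARNING"):
            assert ms.select_mice(cs, 4) == ["m1"]
        assert "using all" in caplog.text


class TestEssentialityScores:
    def test_min_adjusted_p_and_score(self):
        padj = {"m1": 0.01, "m2": 0.2, "m3": 0.05, "m4": 0.5}
        lung = {m: make_gene_result({"A": {"pos_fdr": v}})
                for m, v in padj.items()}
        table = ms.essentiality_scores(comparison_set(lung=lung), list(padj))
        assert table.loc["A", "min_adj_p"] == pytest.approx(0.01)
        assert table.loc["A", "essentiality_score"] == pytest.approx(2.0)
        assert table.loc["A", "final_rank"] == 1

    def test_all_p_one_gives_zero_score(self):
        lung = {"m1": make_gene_result({"A": {"pos_fdr": 1.0}})}
        table = ms.essentiality_scores(comparison_set(lung=lung), ["m1"])
        assert table.loc["A", "essentiality_score"] == 0.0

    def test_gene_missing_in_one_mouse_treated_as_one(self, caplog):
        lung = {
            "m1": make_gene_result({"A": {"pos_fdr": 0.3}, "B": {"pos_fdr": 0.2}}),
            "m2": make_gene_result({"A": {"pos_fdr": 0.6}}),
        }
        with caplog.at_level("WARNING"):
            table = ms.essentiality_scores(comparison_set(lung=lung),
                                           ["m1", "m2"])
        assert "missing" in caplog.text
        assert table.loc["B", "padj_m2"] == 1.0
        assert table.loc["B", "min_adj_p"] == pytest.approx(0.2)

    def test_monotone_decreasing_p_never_worsens_rank(self):
        rng = np.random.default_rng(14)
        genes = [f"G{i:02d}" for i in range(30)]
        lung = {m: make_gene_result(
            {g: {"pos_fdr": rng.uniform(), "pos_p": rng.uniform()}
             for g in genes}) for m in ("m1", "m2")}
        cs = comparison_set(lung=lung)
        base = ms.essentiality_scores(cs, ["m1", "m2"])
        target = genes[17]
        lung["m1"].loc[target, "pos_fdr"] *= 0.01
        improved = ms.essentiality_scores(comparison_set(lung=lung), ["m1", "m2"])
        assert improved.loc[target, "final_rank"] <= base.loc[target, "final_rank"]

    def test_requires_selected_mice_present(self):
        with pytest.raises(ValueError, match="m9"):
            ms.essentiality_scores(
                comparison_set(lung={"m1": make_gene_result({"A": {}})}), ["m9"])


def essentiality_table(entries):
    """{gene: (min_adj_p, final_rank)} -> essentiality frame."""
    out = pd.DataFrame.from_dict(
        {g: {"min_adj_p": p, "final_rank": r} for g, (p, r) in entries.items()},
        orient="index",
    )
    out.index.name = "gene"
    out["essentiality_score"] = -np.log10(out["min_adj_p"])
    return out


class TestCrossLineConcordance:
    def test_intersection_of_top_lists(self):
        a = essentiality_table({"A": (0.01, 1), "B": (0.02, 2), "C": (0.5, 3)})
        b = essentiality_table({"A": (0.01, 2), "B": (0.03, 5), "C": (0.4, 1)})
        res = ms.cross_line_concordance(a, b, sig_threshold=0.05, k=2)
        assert res.concordant == ["A", "B"]
        assert res.top_k == ["A"]  # B is outside line B's top-2
        assert res.combined_rank["A"] == 2

    def test_threshold_one_keeps_whole_universe(self):
        a = essentiality_table({"A": (0.9, 1), "B": (0.99, 2)})
        b = essentiality_table({"A": (0.8, 2), "B": (0.7, 1)})
        res = ms.cross_line_concordance(a, b, sig_threshold=1.0, k=1)
        assert res.concordant == ["A", "B"]

    def test_disjoint_universes_error(self):
        a = essentiality_table({"A": (0.1, 1)})
        b = essentiality_table({"B": (0.1, 1)})
        with pytest.raises(ValueError, match="disjoint"):
            ms.cross_line_concordance(a, b)


class TestLungLiverFilter:
    def two_mouse_set(self, lung_ranks, liver_ranks):
        """ranks: {gene: (neg_rank, pos_rank)} shared by both mice."""
        def table(ranks):
            return make_gene_result({
                g: {"neg_rank": nr, "pos_rank": pr,
                    "pos_p": pr / (len(ranks) + 1.0),
                    "neg_p": nr / (len(ranks) + 1.0)}
                for g, (nr, pr) in ranks.items()
            })
        lung = {m: table(lung_ranks) for m in ("m1", "m2")}
        liver = {m: table(liver_ranks) for m in ("m1", "m2")}
        return comparison_set(lung=lung, liver=liver)

    def test_lung_specific_gene_passes(self):
        cs = self.two_mouse_set(
            lung_ranks={"A": (3, 1), "B": (1, 3), "C": (2, 2)},
            liver_ranks={"A": (1, 3), "B": (2, 2), "C": (3, 1)},
        )
        filt = ms.lung_liver_rank_filter(cs)
        assert bool(filt.loc["A", "passes_filter"])
        assert filt.loc["A", "comprehensive_rank"] == 1

    def test_single_mouse_failure_excludes_gene(self):
        cs = self.two_mouse_set(
            lung_ranks={"A": (3, 1), "B": (1, 3), "C": (2, 2)},
            liver_ranks={"A": (1, 3), "B": (2, 2), "C": (3, 1)},
        )
        # break one inequality for A in one mouse only
        cs.liver["m2"].loc["A", "neg_rank"] = 3
        cs.liver["m2"].loc["C", "neg_rank"] = 1
        filt = ms.lung_liver_rank_filter(cs)
        assert not bool(filt.loc["A", "passes_filter"])
        assert bool(filt.loc["A", "pass_m1"])
        assert np.isnan(filt.loc["A", "comprehensive_rank"])

    def test_missing_liver_table_names_mouse(self):
        cs = self.two_mouse_set(
            lung_ranks={"A": (2, 1), "B": (1, 2)},
            liver_ranks={"A": (1, 2), "B": (2, 1)},
        )
        del cs.liver["m2"]
        with pytest.raises(ValueError, match="m2"):
            ms.lung_liver_rank_filter(cs)

    def test_invariant_under_monotone_p_relabeling(self):
        cs = self.two_mouse_set(
            lung_ranks={"A": (3, 1), "B": (1, 3), "C": (2, 2)},
            liver_ranks={"A": (1, 3), "B": (2, 2), "C": (3, 1)},
        )
        before = ms.lung_liver_rank_filter(cs)
        for store in (cs.lung, cs.liver):
            for tab in store.values():
                for col in ("pos_p", "neg_p"):
                    tab[col] = np.sqrt(tab[col])  # strictly monotone
        after = ms.lung_liver_rank_filter(cs)
        pd.testing.assert_series_equal(before["passes_filter"],
                                       after["passes_filter"])
        pd.testing.assert_series_equal(before["comprehensive_rank"],
                                       after["comprehensive_rank"])

    def test_null_screen_pass_rate_is_small(self):
        # under a pure null the two rank inequalities are each ~Bernoulli(1/2)
        # per mouse and positively correlated, so the all-replicates pass
        # count should sit near or below n/2^R and far below the universe
        cfg = ms.ScreenSimConfig(n_genes=400, sgrnas_per_gene=2, n_mice=5,
                                 seed=21)
        counts, meta, _ = ms.simulate_screen(cfg)
        cs = ms.build_comparison_set(counts, cfg.library(), meta, "SIM1",
                                     ms.RRAConfig(n_perm=150, seed=3),
                                     include_liver=True)
        filt = ms.lung_liver_rank_filter(cs)
        n_pass = int(filt["passes_filter"].sum())
        assert n_pass <= 2 * 400 * 0.5 ** 5  # = 25


class TestPipeline:
    def test_planted_suppressors_dominate_ranking(self, small_screen):
        cfg, counts, meta, truth = small_screen
        cs, ess = ms.analyze_cell_line(counts, cfg.library(), meta, "SIM1",
                                       ms.RRAConfig(n_perm=300, seed=6),
                                       k_mice=2,
                                       lung_preference=truth.lung_preference)
        top2 = set(ess.index[ess["final_rank"] <= 2])
        assert top2 == {"G10", "G20"}
        metrics = ms.recovery_metrics(ess, truth, top_fraction=2 / 60)
        assert metrics["recall"] == 1.0

    def test_unknown_cell_line_rejected(self, small_screen):
        cfg, counts, meta, _ = small_screen
        with pytest.raises(ValueError, match="NOPE"):
            ms.build_comparison_set(counts, cfg.library(), meta, "NOPE",
                                    ms.RRAConfig(n_perm=100))
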