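import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paretohits.screen import (
    Condition,
    HitMatrix,
    ScreenComparisonTable,
    aggregate_desirability,
    build_hit_matrix,
    call_hit,
    consistency_features,
    d_essentiality,
    d_fdr,
    d_lfc,
    d_pvalue,
    lfc_boundary,
    overall_desirability,
    read_comparison_table,
    write_comparison_table,
)


def make_table(rows, condition=None, comparison="CvT"):
    cond = condition or Condition("PC-9", "osimertinib", "KO")
    return ScreenComparisonTable(
        condition=cond, comparison=comparison,
        rows=pd.DataFrame(rows),
    )


class TestPartialRules:
    @pytest.mark.parametrize(
        "fdr,expected", [(0.2, 0.0), (0.05, 1.0), (0.1, 1.0), (0.0, 1.0), (1.0, 0.0)]
    )
    def test_fdr_step(self, fdr, expected):
        assert d_fdr(fdr) == expected

    def test_fdr_out_of_range(self):
        with pytest.raises(ValueError):
            d_fdr(1.5)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, 0.01), (0.2, 0.01), (1e-4, 1.0), (1e-6, 1.0),
         # interior point: t = 1.5/3 = 0.5, d = 0.01 + 0.99 * 0.25
         (10**-2.5, 0.2575)],
    )
    def test_pvalue_curve(self, p, expected):
        assert d_pvalue(p, shape=2.0) == pytest.approx(expected)

    def test_pvalue_curve_matches_direct_formula(self):
        for p in np.logspace(-3.9, -1.01, 17):
            t = (np.log10(0.1) - np.log10(p)) / 3.0
            assert d_pvalue(p, shape=2.0) == pytest.approx(0.01 + 0.99 * t**2)

    @given(st.floats(1e-12, 1.0).filter(lambda p: p > 0))
    def test_pvalue_in_unit_interval(self, p):
        assert 0.0 <= d_pvalue(p) <= 1.0

    @given(st.tuples(st.floats(1e-10, 1.0), st.floats(1e-10, 1.0)))
    def test_pvalue_monotone_non_increasing(self, ps):
        lo, hi = sorted(ps)
        assert d_pvalue(lo) >= d_pvalue(hi)

    def test_pvalue_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            d_pvalue(0.0)

    @pytest.mark.parametrize(
        "vals,mode,expected",
        [([-1, 0, 1], "resistance", 3.0),
         ([-1, 0, 1], "sensitivity", -3.0),
         ([5, 5, 5], "resistance", 5.0)],  # degenerate sd = 0
    )
    def test_lfc_boundary(self, vals, mode, expected):
        assert lfc_boundary(vals, mode) == pytest.approx(expected)

    def test_lfc_boundary_uses_sample_sd(self):
        vals = [0.0, 2.0]  # sample sd sqrt(2), population sd 1
        assert lfc_boundary(vals) == pytest.approx(1.0 + 3 * np.sqrt(2))

    def test_lfc_boundary_needs_two_values(self):
        with pytest.raises(ValueError):
            lfc_boundary([1.0])

    @pytest.mark.parametrize(
        "lfc,boundary,mode,expected",
        [(4.2, 3.0, "resistance", 1.0),
         (2.9, 3.0, "resistance", 0.01),
         (3.0, 3.0, "resistance", 1.0),  # boundary equality is favorable
         (-3.5, -3.0, "sensitivity", 1.0),
         (-2.0, -3.0, "sensitivity", 0.01)],
    )
    def test_lfc_step(self, lfc, boundary, mode, expected):
        assert d_lfc(lfc, boundary, mode) == expected

    @pytest.mark.parametrize(
        "cvp,cvt,lfc,expected",
        [(True, True, 2.0, 0.0),    # essential in both comparisons
         (False, False, -0.5, 0.0),  # negative LFC veto
         (True, False, 1.0, 1.0),
         (False, False, 1.0, 1.0)],
    )
    def test_essentiality_veto(self, cvp, cvt, lfc, expected):
        assert d_essentiality("G", cvp, cvt, lfc) == expected


class TestAggregation:
    @pytest.mark.parametrize(
        "comps,expected",
        [((1.0, 1.0, 1.0), 1.0),
         ((0.25, 1.0), 0.5),
         ((0.9, 0.0, 0.8), 0.0)],
    )
    def test_geometric_mean_examples(self, comps, expected):
        assert aggregate_desirability(comps) == pytest.approx(expected)

    def test_weighted(self):
        # (0.25^3 * 1^1)^(1/4) = 0.25^(3/4)
        assert aggregate_desirability([0.25, 1.0], [3.0, 1.0]) == pytest.approx(
            0.25 ** 0.75
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_desirability([0.5, 0.5], [1.0])

    def test_component_out_of_range(self):
        with pytest.raises(ValueError):
            aggregate_desirability([1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_aggregate_in_unit_interval(self, comps):
        assert 0.0 <= aggregate_desirability(comps) <= 1.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6))
    def test_zero_annihilation(self, comps):
        assert aggregate_desirability(comps + [0.0]) == 0.0


class TestOverallDesirability:
    def _tables(self, genes, lfc, pval, fdr, essential_cvt=None, essential_cvp=None):
        n = len(genes)
        cvt = make_table({
            "gene": genes, "lfc": lfc, "pvalue": pval, "fdr": fdr,
            "essential_flag": essential_cvt or [False] * n,
        })
        cvp = make_table({
            "gene": genes, "lfc": [0.0] * n, "pvalue": [0.5] * n,
            "fdr": [0.5] * n, "essential_flag": essential_cvp or [False] * n,
        }, comparison="CvP")
        return cvt, cvp

    def test_planted_gene_scores_one(self):
        genes = [f"G{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        lfc = list(rng.normal(0, 1, 19)) + [20.0]
        pval = [0.5] * 19 + [1e-5]
        fdr = [0.5] * 19 + [0.01]
        cvt, cvp = self._tables(genes, lfc, pval, fdr)
        res = overall_desirability(cvt, cvp)
        assert res.table.loc["G19", "overall"] == 1.0

    def test_high_fdr_forces_zero_overall(self):
        genes = ["A", "B", "C"]
        cvt, cvp = self._tables(genes, [5.0, 0.1, -0.1], [1e-6, 0.5, 0.5],
                                [0.5, 0.01, 0.01])
        res = overall_desirability(cvt, cvp)
        assert res.table.loc["A", "overall"] == 0.0  # fdr 0.5 annihilates

    def test_null_gene_geometric_mean(self):
        # components (d_fdr, d_pvalue, d_lfc, d_ess) = (1, 0.01, 0.01, 1)
        # -> (1e-4)^(1/4) = 0.1
        genes = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        lfc = list(rng.normal(0, 1, 9)) + [abs(rng.normal())]
        lfc[-1] = 0.5  # below boundary, positive
        cvt, cvp = self._tables(genes, lfc, [0.5] * 9 + [0.5],
                                [0.5] * 9 + [0.01])
        res = overall_desirability(cvt, cvp)
        row = res.table.loc["G9"]
        assert (row["d_fdr"], row["d_pvalue"], row["d_lfc"],
                row["d_essentiality"]) == (1.0, 0.01, 0.01, 1.0)
        assert row["overall"] == pytest.approx(0.1)

    def test_sensitivity_mode_uses_three_components(self):
        genes = [f"G{i}" for i in range(40)]
        lfc = [-10.0] + list(np.linspace(-1, 1, 39))  # planted well below mean-3sd
        cvt, _ = self._tables(genes, lfc, [1e-5] + [0.5] * 39,
                              [0.01] + [0.5] * 39)
        res = overall_desirability(cvt, None, mode="sensitivity")
        assert res.table.loc["G0", "overall"] == 1.0
        assert np.isnan(res.table.loc["G0", "d_essentiality"])

    def test_resistance_requires_cvp(self):
        cvt, _ = self._tables(["A", "B"], [0.1, 0.2], [0.5, 0.5], [0.5, 0.5])
        with pytest.raises(ValueError, match="CvP"):
            overall_desirability(cvt, None, mode="resistance")

    def test_disjoint_gene_universes_error(self):
        cvt, _ = self._tables(["A", "B"], [0.1, 0.2], [0.5, 0.5], [0.5, 0.5])
        cvp = make_table({
            "gene": ["X", "Y"], "lfc": [0.0, 0.0], "pvalue": [0.5, 0.5],
            "fdr": [0.5, 0.5], "essential_flag": [False, False],
        }, comparison="CvP")
        with pytest.raises(ValueError, match="no genes"):
            overall_desirability(cvt, cvp)

    def test_row_permutation_invariance(self):
        genes = [f"G{i}" for i in range(15)]
        rng = np.random.default_rng(3)
        lfc = list(rng.normal(0, 1, 15))
        pv = list(rng.uniform(0, 1, 15))
        fd = list(rng.uniform(0, 1, 15))
        cvt, cvp = self._tables(genes, lfc, pv, fd)
        res1 = overall_desirability(cvt, cvp)
        perm = rng.permutation(15)
        cvt2 = make_table(cvt.rows.iloc[perm].reset_index(drop=True))
        cvp2 = make_table(cvp.rows.iloc[perm].reset_index(drop=True),
                          comparison="CvP")
        res2 = overall_desirability(cvt2, cvp2)
        pd.testing.assert_frame_equal(
            res1.table.sort_index(), res2.table.sort_index()
        )


class TestHitCalling:
    @pytest.mark.parametrize(
        "desi,fdr,expected",
        [(0.8, 0.05, True), (0.7, 0.05, False), (0.9, 0.1, False),
         (0.71, 0.09, True), (0.0, 0.0, False)],
    )
    def test_thresholds_are_strict(self, desi, fdr, expected):
        assert call_hit(desi, fdr) is expected


def toy_hit_matrix(hits_by_gene):
    conds = {
        "PC-9|gefitinib|KO": Condition("PC-9", "gefitinib", "KO"),
        "PC-9|osimertinib|KO": Condition("PC-9", "osimertinib", "KO"),
        "HCC827|osimertinib|KO": Condition("HCC827", "osimertinib", "KO"),
        "PC-9|gefitinib|activation": Condition("PC-9", "gefitinib", "activation"),
    }
    genes = sorted(hits_by_gene)
    calls = pd.DataFrame(
        {lb: [lb in hits_by_gene[g] for g in genes] for lb in conds},
        index=genes,
    )
    return HitMatrix(calls=calls, conditions=conds)


class TestConsistencyFeatures:
    def test_emits_exactly_seven_features(self):
        hm = toy_hit_matrix({"A": set()})
        feats = consistency_features(hm)
        assert feats.shape[1] == 7

    def test_hand_counted_toy(self):
        hm = toy_hit_matrix({
            "A": {"PC-9|gefitinib|KO", "HCC827|osimertinib|KO"},
            "B": set(),
            "C": {"PC-9|gefitinib|KO", "PC-9|osimertinib|KO"},
        })
        f = consistency_features(hm)
        # A: two KO conditions in two cell lines, two treatments
        assert list(f.loc["A"]) == [2, 2, 2, 0, 0, 0, 2]
        # B: hit nowhere
        assert list(f.loc["B"]) == [0, 0, 0, 0, 0, 0, 0]
        # C: two conditions, one cell line -> full_screen counts distinct lines
        assert f.loc["C", "KO_n_cell_lines_hit"] == 1
        assert f.loc["C", "full_screen"] == 1

    def test_cross_technology_full_screen(self):
        hm = toy_hit_matrix({
            "A": {"HCC827|osimertinib|KO", "PC-9|gefitinib|activation"},
        })
        f = consistency_features(hm)
        assert f.loc["A", "full_screen"] == 2  # distinct lines across techs

    def test_counts_bounded_by_column_counts(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(30)]
        hm = toy_hit_matrix({
            g: {lb for lb in ["PC-9|gefitinib|KO", "PC-9|osimertinib|KO",
                              "HCC827|osimertinib|KO",
                              "PC-9|gefitinib|activation"]
                if rng.uniform() < 0.5}
            for g in genes
        })
        f = consistency_features(hm)
        assert (f["KO_n_conditions_hit"] <= 3).all()
        assert (f["activation_n_conditions_hit"] <= 1).all()
        assert (f["full_screen"] <= 2).all()

    def test_unknown_technology_rejected(self):
        conds = {"x": Condition("PC-9", "gef", "CRISPRi")}
        calls = pd.DataFrame({"x": [True]}, index=["A"])
        with pytest.raises(ValueError, match="technology"):
            consistency_features(HitMatrix(calls=calls, conditions=conds))


class TestComparisonTableIO:
    def test_round_trip(self, tmp_path):
        t = make_table({
            "gene": ["A", "B"], "lfc": [1.0, -0.5], "pvalue": [0.01, 0.9],
            "fdr": [0.1, 0.95], "essential_flag": [False, True],
        })
        p = tmp_path / "cvt.tsv"
        write_comparison_table(t, p)
        back = read_comparison_table(p)
        assert back.condition == t.condition and back.comparison == "CvT"
        pd.testing.assert_frame_equal(back.rows, t.rows)

    def test_pvalue_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="pvalue"):
            make_table({
                "gene": ["A"], "lfc": [0.0], "pvalue": [1.2], "fdr": [0.5],
                "essential_flag": [False],
            })
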