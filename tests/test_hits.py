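"""sgRNA hit calling, top-k tables, expression cross-check, cumulative score."""

import numpy as np
import pandas as pd
import pytest

from dropoutscreen.hits import (
    call_hits,
    cumulative_score,
    depletion_viability_correlation,
    expression_crosscheck,
    hit_genes,
    ranked_table,
)
from dropoutscreen.io import ExpressionTable, SgRnaLibrary

from conftest import make_fc, make_library


def fc_from_values(values, seed_lib=None):
    lib = seed_lib or make_library({f"G{i:04d}": 1 for i in range(len(values))})
    return make_fc(lib, {"d14": list(values)})


class TestCallHits:
    def test_exact_count_without_ties(self):
        rng = np.random.default_rng(1)
        neg = -rng.uniform(0.01, 5, 200)
        pos = rng.uniform(0.01, 5, 100)
        fc = fc_from_values(np.concatenate([neg, pos]))
        res = call_hits(fc, "d14", 0.05)
        assert res.n_depleted == 200
        assert res.n_hits == 10  # ceil(0.05 * 200)
        assert res.cutoff < 0

    def test_no_depleted_guides_is_an_error(self):
        fc = fc_from_values([0.5, 1.0, 0.0, 2.0])
        with pytest.raises(ValueError, match="no depleted"):
            call_hits(fc, "d14")

    def test_cutoff_matches_sort_oracle_on_fixed_seed_values(self):
        rng = np.random.default_rng(2024)
        values = rng.normal(0, 2, 1000)
        fc = fc_from_values(values)
        res = call_hits(fc, "d14", 0.05)
        depleted = np.sort(values[values < 0])
        m = int(np.ceil(0.05 * len(depleted)))
        assert res.cutoff == pytest.approx(depleted[m - 1])
        assert res.n_hits == (values <= depleted[m - 1]).sum()

    def test_ties_at_cutoff_all_included(self):
        values = [-2.0, -2.0, -2.0, -1.0] + [-0.5] * 36 + [1.0] * 10
        fc = fc_from_values(values)
        res = call_hits(fc, "d14", 0.05)  # ceil(0.05*40) = 2 -> cutoff -2.0
        assert res.cutoff == -2.0
        assert res.n_hits == 3  # all three tied guides

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 100)
        ref = call_hits(fc_from_values(values), "d14")
        perm = rng.permutation(100)
        lib = make_library({f"G{i:04d}": 1 for i in range(100)})
        ids = [lib.sgrna_ids[i] for i in perm]
        lib2 = SgRnaLibrary([lib[i] for i in ids])
        shuffled = call_hits(make_fc(lib2, {"d14": values[perm].tolist()}), "d14")
        assert {i.rsplit("_", 1)[0] for i in ref.hits} == {
            i.rsplit("_", 1)[0] for i in shuffled.hits
        }
        assert ref.cutoff == pytest.approx(shuffled.cutoff)

    def test_raising_fraction_never_shrinks_hit_set(self):
        rng = np.random.default_rng(4)
        fc = fc_from_values(rng.normal(0, 1, 300))
        previous = set()
        for fraction in (0.01, 0.05, 0.1, 0.25, 0.5, 1.0):
            hits = call_hits(fc, "d14", fraction).hits
            assert previous <= hits
            previous = hits


class TestRankedTable:
    @pytest.fixture
    def tagged_fc(self):
        lib = make_library({"K1": 1, "K2": 1, "N1": 1, "N2": 1, "N3": 1},
                           tags={"kinase": {"K1", "K2"}})
        return make_fc(lib, {"d14": [-1.0, -3.0, -5.0, -2.0, 0.5]})

    def test_restriction_and_truncation(self, tagged_fc):
        table = ranked_table(tagged_fc, "d14", tag="kinase", k=20)
        assert list(table["gene"]) == ["K2", "K1"]  # k > tagged count: full list
        assert list(table["log2fc"]) == [-3.0, -1.0]

    def test_tagged_table_is_subsequence_of_unrestricted(self, tagged_fc):
        full = list(ranked_table(tagged_fc, "d14", k=20)["sgrna_id"])
        tagged = list(ranked_table(tagged_fc, "d14", tag="kinase", k=20)["sgrna_id"])
        it = iter(full)
        assert all(s in it for s in tagged)

    def test_tie_at_kth_value_resolved_by_id(self):
        lib = make_library({"A": 1, "B": 1, "C": 1})
        fc = make_fc(lib, {"d14": [-1.0, -1.0, -5.0]})
        table = ranked_table(fc, "d14", k=2)
        assert list(table["sgrna_id"]) == ["C_g1", "A_g1"]

    def test_unknown_tag_is_error(self, tagged_fc):
        with pytest.raises(KeyError, match="phosphatase"):
            ranked_table(tagged_fc, "d14", tag="phosphatase")


class TestExpressionCrosscheck:
    def expr(self, mapping, threshold=1.0):
        return ExpressionTable(pd.Series(mapping, dtype=float), threshold)

    def test_simple_fraction(self):
        genes = [f"G{i}" for i in range(10)]
        table = self.expr({g: 5.0 for g in genes} | {"G0": 0.2})
        frac, groups = expression_crosscheck(genes, table)
        assert frac == pytest.approx(0.10)
        assert groups["not_expressed"] == ["G0"]

    def test_all_expressed(self):
        genes = ["A", "B", "C"]
        frac, _ = expression_crosscheck(genes, self.expr({g: 2.0 for g in genes}))
        assert frac == 0.0

    def test_unmeasured_genes_excluded_from_denominator(self):
        genes = [f"G{i}" for i in range(10)]
        measured = {f"G{i}": 5.0 for i in range(8)} | {"G0": 0.2}
        frac, groups = expression_crosscheck(genes, self.expr(measured))
        assert frac == pytest.approx(1 / 8)
        assert sorted(groups["unmeasured"]) == ["G8", "G9"]

    def test_empty_hit_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            expression_crosscheck([], self.expr({"A": 1.0}))


class TestCumulativeScore:
    def lib3(self, tags=None):
        return make_library({"EGFR": 3, "OTHER": 3, "PAN": 3}, tags=tags)

    def test_sums_most_depleted_guide_across_timepoints(self):
        # per-timepoint best guides -5.61 / -4.88 / -5.49 -> -15.98
        lib = self.lib3()
        fc = make_fc(
            lib,
            {
                "d14": [-5.61, 0.3, 0.1, 0.0, 0.1, 0.2, -1.0, 0.0, 0.0],
                "d21": [-4.88, 0.2, 0.4, 0.1, 0.0, 0.0, -1.0, 0.0, 0.0],
                "d28": [-5.49, 0.0, 0.3, 0.0, 0.2, 0.0, -1.0, 0.0, 0.0],
            },
        )
        cum = cumulative_score(fc)
        assert cum["EGFR"] == pytest.approx(-15.98)
        assert list(cum.index)[0] == "EGFR"  # ranked ascending

    def test_filters_remove_essential_panlethal_and_unexpressed(self):
        lib = self.lib3(tags={"published_essential": {"OTHER"}})
        fc = make_fc(lib, {"d14": [-2.0] * 9})
        expr = ExpressionTable(
            pd.Series({"EGFR": 10.0, "OTHER": 10.0, "PAN": 10.0}), 1.0
        )
        cum = cumulative_score(
            fc,
            essential_genes=lib.genes_with_tag("published_essential"),
            other_screen_hits={"PAN"},
            expr=expr,
        )
        assert list(cum.index) == ["EGFR"]

    def test_unexpressed_gene_dropped(self):
        fc = make_fc(self.lib3(), {"d14": [-2.0] * 9})
        expr = ExpressionTable(
            pd.Series({"EGFR": 10.0, "OTHER": 0.0, "PAN": 10.0}), 1.0
        )
        assert "OTHER" not in cumulative_score(fc, expr=expr).index

    def test_single_timepoint_equals_summarizer_output(self):
        fc = make_fc(self.lib3(), {"d14": [-3.0, -1.0, 2.0, 0.5, 0.7, 0.9,
                                           -2.0, 1.0, 0.0]})
        cum = cumulative_score(fc)
        assert cum["EGFR"] == -3.0
        assert cum["OTHER"] == 0.5
        assert cum["PAN"] == -2.0

    def test_zero_gene_scores_zero(self):
        fc = make_fc(self.lib3(), {"d14": [0.0] * 9, "d21": [0.0] * 9})
        assert cumulative_score(fc)["EGFR"] == 0.0


class TestViabilityCorrelation:
    def test_perfect_lines(self):
        assert depletion_viability_correlation(
            [1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert depletion_viability_correlation(
            [1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_hand_computed_four_pairs(self):
        # textbook formula by hand on x=(1,2,3,5), y=(2,1,4,6)
        r = depletion_viability_correlation([1, 2, 3, 5], [2, 1, 4, 6])
        assert r == pytest.approx(0.9022436386781062, abs=1e-12)

    def test_fewer_than_three_pairs_is_error(self):
        with pytest.raises(ValueError, match="3"):
            depletion_viability_correlation([1, 2], [3, 4])


class TestHitGenes:
    def test_controls_never_become_hit_genes(self):
        lib = make_library({"A": 1, "B": 1}, n_controls=2)
        fc = make_fc(lib, {"d14": [-5.0, 1.0, -4.0, 0.0]})
        res = call_hits(fc, "d14", fraction=1.0)
        assert hit_genes(fc, res) == {"A"}
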