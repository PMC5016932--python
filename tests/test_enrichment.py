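"""Per-gene summarization, one-tailed KS tests, BH, and top-set selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dropoutscreen.enrichment import (
    bh_adjust,
    enrich,
    ks_one_tailed,
    select_top_sets,
    summarize_gene,
    summarize_gene_values,
)
from dropoutscreen.io import GeneSetCollection

from conftest import make_fc, make_library


class TestSummarizeGene:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((-3, 1, 2), -3.0),
            ((0.5,), 0.5),
            ((-2, 2), -2.0),  # exact magnitude tie goes negative
            ((1, -1, 3), 3.0),
        ],
    )
    def test_max_absolute_signed(self, values, expected):
        assert summarize_gene(values) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize_gene([])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=200)
    def test_result_is_a_member_with_maximal_magnitude(self, values):
        out = summarize_gene(values)
        assert out in values
        assert abs(out) == max(abs(v) for v in values)

    def test_per_gene_vector_from_fold_changes(self):
        lib = make_library({"A": 3, "B": 2}, n_controls=1)
        fc = make_fc(lib, {"d14": [-3.0, 1.0, 2.0, 0.5, -0.2, 9.0]})
        values = summarize_gene_values(fc, "d14")
        assert values.to_dict() == {"A": -3.0, "B": 0.5}  # controls excluded


class TestKsOneTailed:
    def test_identical_samples_give_zero_statistic(self):
        d, p = ks_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "neg")
        assert d == 0.0 and p == 1.0

    def test_full_separation_closed_form(self):
        d, p = ks_one_tailed([-10, -9, -8], [1, 2, 3], "neg")
        assert d == 1.0
        assert p == pytest.approx(math.exp(-3.0))

    def test_wrong_direction_sees_nothing(self):
        d, p = ks_one_tailed([-10, -9, -8], [1, 2, 3], "pos")
        assert d == 0.0 and p == 1.0

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a = rng.normal(-1, 1, 40)
        b = rng.normal(0, 1, 200)
        d_ref, _ = ks_one_tailed(a, b, "neg")
        for f in (lambda x: 3 * x + 7, np.exp, lambda x: x ** 3):
            d_t, _ = ks_one_tailed(f(a), f(b), "neg")
            assert d_t == pytest.approx(d_ref, abs=1e-12)

    def test_exact_permutation_agrees_with_enumeration_brute_force(self):
        a = [-2.0, -1.5, 0.2]
        b = [0.1, 0.5, 1.0, 1.5, -0.3]
        d, p = ks_one_tailed(a, b, "neg", method="permutation")
        # independent brute force over all C(8,3) splits
        from itertools import combinations

        pooled = a + b
        count = 0
        total = 0
        for chosen in combinations(range(8), 3):
            sa = np.array([pooled[i] for i in chosen])
            sb = np.array([pooled[i] for i in range(8) if i not in chosen])
            xs = np.sort(np.concatenate([sa, sb]))
            fa = np.searchsorted(np.sort(sa), xs, side="right") / 3
            fb = np.searchsorted(np.sort(sb), xs, side="right") / 5
            if max(0.0, np.max(fa - fb)) >= d - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total)

    def test_asymptotic_p_is_conservative_under_the_null(self):
        # fraction of null sets with p < alpha stays near or below alpha
        rng = np.random.default_rng(99)
        background = rng.normal(0, 1, 2000)
        alpha = 0.05
        rejected = 0
        R = 300
        for _ in range(R):
            idx = rng.choice(2000, size=30, replace=False)
            mask = np.zeros(2000, dtype=bool)
            mask[idx] = True
            _, p = ks_one_tailed(background[mask], background[~mask], "neg")
            rejected += p < alpha
        bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / R)
        assert rejected / R <= bound

    def test_empty_side_is_error(self):
        with pytest.raises(ValueError):
            ks_one_tailed([], [1.0], "neg")


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [-0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_q_at_least_p_and_monotone_when_sorted(self, ps):
        ps = sorted(ps)
        qs = bh_adjust(ps)
        assert np.all(qs >= np.asarray(ps) - 1e-15)
        assert np.all(np.diff(qs) >= -1e-15)
        assert np.all(qs <= 1.0 + 1e-15)


def values_series(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0, 1, n), index=[f"G{i:04d}" for i in range(n)])


class TestEnrich:
    def test_planted_depleted_set_hits_closed_form(self):
        values = values_series()
        planted = [f"G{i:04d}" for i in range(30)]
        values[planted] = values.min() - 1 - np.arange(30) * 0.1
        sets = GeneSetCollection({"planted": set(planted)}, (20, 2000))
        row = enrich(values, sets).loc["planted"]
        m, n = 30, 170
        assert row["d_neg"] == 1.0
        assert row["p_neg"] == pytest.approx(math.exp(-2 * m * n / (m + n)))
        assert row["direction"] == "neg"
        assert row["q_neg"] == pytest.approx(row["p_neg"])  # single set

    def test_null_set_is_unremarkable(self):
        values = values_series(seed=1)
        sets = GeneSetCollection(
            {"null": set(values.sample(30, random_state=7).index)}, (20, 2000)
        )
        row = enrich(values, sets).loc["null"]
        assert row["p_neg"] > 0.001 and row["p_pos"] > 0.001

    def test_sets_outside_bounds_are_absent(self):
        values = values_series()
        sets = GeneSetCollection(
            {"tiny": {"G0000", "G0001"}, "ok": set(values.index[:25])}, (20, 2000)
        )
        table = enrich(values, sets)
        assert list(table.index) == ["ok"]

    def test_unmeasured_genes_dropped_before_size_filter(self):
        values = values_series(n=50)
        genes = set(values.index[:15]) | {f"UNMEASURED{i}" for i in range(10)}
        sets = GeneSetCollection({"s": genes}, (16, 2000))
        with pytest.raises(ValueError, match="no gene set"):
            enrich(values, sets)

    def test_background_is_complement(self):
        values = values_series(n=40)
        in_set = set(values.index[:20])
        sets = GeneSetCollection({"s": in_set}, (5, 2000))
        row = enrich(values, sets).loc["s"]
        assert row["m"] == 20 and row["n"] == 20

    def test_zero_retained_sets_is_error(self):
        with pytest.raises(ValueError):
            enrich(values_series(), GeneSetCollection({}, (20, 2000)))


class TestSelectTopSets:
    def rows(self, neglog_neg):
        return pd.DataFrame(
            {
                "p_neg": 10.0 ** (-np.asarray(neglog_neg)),
                "p_pos": np.ones(len(neglog_neg)),
            },
            index=[f"S{i:03d}" for i in range(len(neglog_neg))],
        )

    def test_nothing_above_threshold_gives_empty_selection(self):
        out = select_top_sets(self.rows([1.0, 5.0, 6.9]), k=20, threshold=7)
        assert out["neg"].empty and out["pos"].empty

    def test_truncated_to_k_best_first(self):
        out = select_top_sets(self.rows(list(np.linspace(8, 20, 25))), k=20,
                              threshold=7)
        assert len(out["neg"]) == 20
        assert out["neg"]["neglog10p_dir"].is_monotonic_decreasing
        assert out["neg"]["neglog10p_dir"].iloc[0] == pytest.approx(20.0)

    def test_exactly_at_threshold_excluded(self):
        out = select_top_sets(self.rows([7.0, 7.1]), k=20, threshold=7)
        assert list(out["neg"].index) == ["S001"]
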