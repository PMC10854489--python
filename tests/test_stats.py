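"""Usage, PUI, chi-square/BH/Wilcoxon statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from sc3apa.stats import (
    benjamini_hochberg,
    chi_square_independence,
    classify_events,
    diff_apa_all,
    gene_usage_per_cell,
    mean_proximal_pui,
    proximal_usage,
    wilcoxon_rank_sum,
)
from sc3apa.quantify import aggregate_by_cluster
from tests.conftest import make_peak_counts


class TestProximalUsage:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 0], 1.0), ([3, 9], 0.25), ([2, 1, 1], 0.5)],
    )
    def test_values(self, counts, expected):
        assert proximal_usage(np.array(counts)) == expected

    def test_zero_total_undefined(self):
        assert math.isnan(proximal_usage(np.array([0, 0])))

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            proximal_usage(np.array([5]))

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_usage_fractions_sum_to_one(self, counts):
        arr = np.array(counts)
        if arr.sum() == 0:
            assert math.isnan(proximal_usage(arr))
        else:
            fracs = arr / arr.sum()
            assert np.isclose(fracs.sum(), 1.0)
            assert proximal_usage(arr) == pytest.approx(fracs[0])


def brute_force_chi_square(table):
    """Explicit expected-count loop: sum (O-E)^2/E over all cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestChiSquare:
    def test_flat_table_statistic_zero(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_two_by_two_closed_form(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 6.667 for [[20,10],[10,20]]
        stat, df, _ = chi_square_independence([[20, 10], [10, 20]])
        assert round(stat, 3) == 6.667 and df == 1

    def test_three_peaks_two_groups_df(self):
        _, df, _ = chi_square_independence([[10, 5], [8, 9], [3, 12]])
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            shape = (rng.integers(2, 5), rng.integers(2, 4))
            table = rng.integers(1, 80, size=shape)
            stat, _, _ = chi_square_independence(table)
            assert abs(stat - brute_force_chi_square(table)) <= 1e-10


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_q_dominates_p_and_is_monotone_in_sorted_order(self, ps):
        q = benjamini_hochberg(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_step_up_formula(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, min(1.0, m * p[idx] / rank))
            expected[idx] = running
        assert np.allclose(benjamini_hochberg(p), expected)


class TestWilcoxon:
    def test_separated_samples_reference_value(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert round(res.p_two_sided, 3) == 0.081

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(1.0, size=25)
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(y, x)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)
        assert a.u_statistic + b.u_statistic == len(x) * len(y)

    def test_identical_samples_near_zero_z(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = wilcoxon_rank_sum(x, x)
        assert res.z == pytest.approx(0.0, abs=0.3)
        assert res.p_two_sided > 0.5

    def test_constant_equal_samples_p_one(self):
        res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert res.p_two_sided == 1.0 and res.z == 0.0

    def test_u_within_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=rng.integers(1, 15))
            y = rng.normal(size=rng.integers(1, 15))
            res = wilcoxon_rank_sum(x, y)
            assert 0 <= res.u_statistic <= len(x) * len(y)

    def test_shift_increases_z_until_saturation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y0 = rng.normal(size=30)
        zs = [wilcoxon_rank_sum(x, y0 + shift).z for shift in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b >= a - 1e-12 for a, b in zip(zs, zs[1:]))
        assert zs[-1] > zs[0]

    def test_matches_reference_continuity_corrected_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 40))
            y = rng.normal(0.3, size=rng.integers(3, 40))
            ours = wilcoxon_rank_sum(x, y)
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
            )
            assert abs(ours.p_two_sided - ref.pvalue) <= 1e-8
            assert ours.u_statistic == pytest.approx(ref.statistic)

    def test_continuity_flag_drops_correction(self):
        x, y = [1, 2, 3], [4, 5, 6]
        with_c = wilcoxon_rank_sum(x, y, continuity=True)
        without = wilcoxon_rank_sum(x, y, continuity=False)
        assert without.z > with_c.z


class TestPui:
    def two_gene_counts(self):
        # gene gA usage per cell: B1 1.0, B2 0.5; gene gB usage: B1 0.5, B2 1.0
        matrix = [
            [4, 2],  # gA|1
            [0, 2],  # gA|2
            [2, 6],  # gB|1
            [2, 0],  # gB|2
        ]
        return make_peak_counts(
            matrix, [("gA", 1), ("gA", 2), ("gB", 1), ("gB", 2)],
            ["B1", "B2"], {"B1": "c1", "B2": "c2"},
        )

    def test_gene_usage_per_cell(self):
        pc = self.two_gene_counts()
        assert np.allclose(gene_usage_per_cell(pc, "gA"), [1.0, 0.5])

    def test_raw_mode_mean(self):
        pc = self.two_gene_counts()
        out = mean_proximal_pui(pc, mode="raw", min_genes_per_cell=1)
        assert np.allclose(out["mean_proximal_pui"], [0.75, 0.75])
        assert list(out["n_genes_used"]) == [2, 2]

    def test_standardized_mode_skips_zero_variance_gene(self):
        matrix = [
            [4, 2],  # gA usage 1.0 / 0.5 (informative)
            [0, 2],
            [3, 5],  # gB usage 1.0 / 1.0 (zero variance -> skipped)
            [0, 0],
        ]
        pc = make_peak_counts(
            matrix, [("gA", 1), ("gA", 2), ("gB", 1), ("gB", 2)],
            ["B1", "B2"], {"B1": "c1", "B2": "c2"},
        )
        out = mean_proximal_pui(pc, mode="standardized", min_genes_per_cell=1)
        assert list(out["n_genes_used"]) == [1, 1]

    def test_min_genes_per_cell_omits_cells(self):
        pc = self.two_gene_counts()
        out = mean_proximal_pui(pc, mode="raw", min_genes_per_cell=3)
        assert out.empty

    def test_undefined_cells_excluded(self):
        matrix = [[4, 0], [2, 0]]
        pc = make_peak_counts(matrix, [("gA", 1), ("gA", 2)], ["B1", "B2"],
                              {"B1": "c1", "B2": "c2"})
        out = mean_proximal_pui(pc, mode="raw", min_genes_per_cell=1)
        assert list(out["barcode"]) == ["B1"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            mean_proximal_pui(self.two_gene_counts(), mode="median")


class TestDiffApaAndClassify:
    def cluster_counts(self, a_counts, b_counts):
        matrix = np.column_stack([a_counts, b_counts])
        pc = make_peak_counts(matrix, [("gA", 1), ("gA", 2)], ["B1", "B2"],
                              {"B1": "groupA", "B2": "groupB"})
        return aggregate_by_cluster(pc)

    def test_flat_table_not_significant(self):
        cc = self.cluster_counts([10, 10], [10, 10])
        tests = diff_apa_all(cc, ["groupA"], ["groupB"])
        row = tests.iloc[0]
        assert row["statistic"] == 0.0 and row["p"] == 1.0 and row["call"] == "ns"

    def test_shortened_call_and_delta_sign(self):
        cc = self.cluster_counts([20, 180], [180, 20])
        tests = diff_apa_all(cc, ["groupA"], ["groupB"])
        row = tests.iloc[0]
        assert row["call"] == "shortened" and row["delta_proximal"] > 0
        swapped = diff_apa_all(cc, ["groupB"], ["groupA"]).iloc[0]
        assert swapped["call"] == "lengthened" and swapped["delta_proximal"] < 0

    def test_zero_margin_gene_untested(self):
        cc = self.cluster_counts([0, 10], [0, 20])
        tests = diff_apa_all(cc, ["groupA"], ["groupB"])
        assert tests.iloc[0]["call"] == "untested"

    def test_classify_counts_and_ratio(self):
        tests = pd.DataFrame(
            {
                "q": [0.01, 0.01, 0.01, 0.2, np.nan],
                "delta_proximal": [0.3, 0.4, -0.2, 0.5, 0.1],
            }
        )
        summary = classify_events(tests, alpha=0.05)
        assert summary == {"n_shortened": 2, "n_lengthened": 1, "ratio": 2.0}

    def test_classify_no_significant(self):
        tests = pd.DataFrame({"q": [0.5], "delta_proximal": [0.3]})
        summary = classify_events(tests)
        assert summary["n_shortened"] == 0 and math.isnan(summary["ratio"])

    def test_classify_one_shortened_ratio_undefined(self):
        tests = pd.DataFrame({"q": [0.01], "delta_proximal": [0.3]})
        summary = classify_events(tests)
        assert summary["n_shortened"] == 1 and math.isnan(summary["ratio"])
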