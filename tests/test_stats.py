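"""Median/IQR conventions, Mann-Whitney U, and the LOT comparison table."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from neohai.stats import lot_comparison, mann_whitney_u, median_iqr


class TestMedianIqr:
    def test_tukey_hinges_on_odd_sample(self):
        s = median_iqr([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)

    def test_constant_sample(self):
        s = median_iqr([7, 7, 7])
        assert (s.q1, s.median, s.q3) == (7, 7, 7)

    def test_single_value(self):
        s = median_iqr([9])
        assert (s.q1, s.median, s.q3) == (9, 9, 9)
        assert s.sd == 0.0

    def test_even_sample_hinges_include_middle_pairs(self):
        # n=6: halves of size 3; hinges are the middles of each half
        s = median_iqr([1, 2, 3, 4, 5, 6])
        assert (s.q1, s.median, s.q3) == (2, 3.5, 5)

    def test_linear_interpolation_option(self):
        s = median_iqr([1, 2, 3, 4], method="linear")
        assert s.q1 == pytest.approx(np.percentile([1, 2, 3, 4], 25))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            xs = rng.normal(size=rng.integers(1, 30))
            s = median_iqr(xs)
            assert s.q1 <= s.median <= s.q3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


def brute_force_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by literal enumeration of assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = rankdata(pooled)
    mu = n_a * len(b) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    dev = abs(u_obs - mu)
    hits = total = 0
    for subset in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        hits += abs(u_of(subset) - mu) >= dev - 1e-9
    return hits / total


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        result = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert result.u == 0.0
        assert result.p_value == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_constant_groups_tie_completely(self):
        result = mann_whitney_u([5, 5, 5], [5, 5, 5, 5], mode="exact")
        assert result.u == pytest.approx(3 * 4 / 2)
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_literal_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=6).astype(float)  # ties guaranteed likely
        b = rng.integers(0, 5, size=7).astype(float)
        result = mann_whitney_u(a, b, mode="exact")
        assert result.p_value == pytest.approx(brute_force_exact_p(a, b), abs=1e-12)

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=8)
        b = rng.normal(loc=0.8, size=8)
        ours = mann_whitney_u(a, b, mode="exact")
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_approx_close_to_exact_at_eight_per_arm(self):
        # agreement is data-dependent: check the typical (median) deviation
        # over replicates rather than a single draw
        rng = np.random.default_rng(6)
        deviations = []
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(loc=0.5, size=8)
            exact = mann_whitney_u(a, b, mode="exact").p_value
            approx = mann_whitney_u(a, b, mode="normal_approx").p_value
            deviations.append(abs(exact - approx))
        assert float(np.median(deviations)) < 0.01
        assert max(deviations) < 0.03

    def test_exact_and_approx_converge_at_fifteen_per_arm(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=15)
        b = rng.normal(loc=0.4, size=15)
        exact = mann_whitney_u(a, b, mode="exact", max_exact_n=40).p_value
        approx = mann_whitney_u(a, b, mode="normal_approx").p_value
        assert abs(exact - approx) < 0.01

    def test_exact_over_bound_directs_to_approx(self):
        with pytest.raises(ValueError, match="normal_approx"):
            mann_whitney_u(np.arange(30), np.arange(30), mode="exact", max_exact_n=40)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestLotComparison:
    def toy_inputs(self):
        observed = [3.0, 2.0, 7.0, 9.0, 3.0, 5.0]
        theoretical = [0.0, 0.0, 7.0, 9.0, 1.0, None]
        labels = ["none", "none", "presumed", "proven", "none", "presumed"]
        return observed, theoretical, labels

    def test_toy_table_cell_by_cell(self):
        observed, theoretical, labels = self.toy_inputs()
        table = lot_comparison(observed, theoretical, labels)
        no_hai = table.loc["no_hai"]
        assert no_hai["n"] == 3 and no_hai["n_excluded"] == 0
        assert no_hai["observed_median"] == 3.0
        assert (no_hai["observed_q1"], no_hai["observed_q3"]) == (2.5, 3.0)
        assert no_hai["theoretical_median"] == 0.0
        any_hai = table.loc["any_hai"]
        assert any_hai["n"] == 2 and any_hai["n_excluded"] == 1  # pairwise exclusion
        assert any_hai["observed_median"] == 8.0
        assert any_hai["theoretical_median"] == 8.0
        overall = table.loc["overall"]
        assert overall["n"] == 5 and overall["n_excluded"] == 1
        assert overall["observed_median"] == 3.0
        assert overall["theoretical_median"] == 1.0

    def test_group_sizes_sum_to_cohort_minus_exclusions(self):
        observed, theoretical, labels = self.toy_inputs()
        table = lot_comparison(observed, theoretical, labels)
        assert (
            table.loc["no_hai", "n"]
            + table.loc["proven", "n"]
            + table.loc["presumed", "n"]
            == table.loc["overall", "n"]
        )
        assert table.loc["overall", "n"] + table.loc["overall", "n_excluded"] == 6

    def test_identical_vectors_give_p_one(self):
        observed = [3.0, 5.0, 7.0, 9.0]
        table = lot_comparison(observed, list(observed), ["none"] * 4)
        assert table.loc["no_hai", "p_value"] == pytest.approx(1.0)

    def test_empty_group_reported_with_nan_summaries(self):
        table = lot_comparison([3.0], [0.0], ["none"])
        assert table.loc["proven", "n"] == 0
        assert math.isnan(table.loc["proven", "observed_median"])

    def test_wilcoxon_alternative_runs(self):
        observed, theoretical, labels = self.toy_inputs()
        table = lot_comparison(observed, theoretical, labels, test="wilcoxon")
        assert table.loc["any_hai", "p_value"] == pytest.approx(1.0)

    def test_unclassifiable_episodes_excluded(self):
        table = lot_comparison([3.0, 4.0], [0.0, 0.0], ["none", None])
        assert table.loc["overall", "n"] == 1
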