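"""Exhaustive CHAID: chi-square, category merging, tree growth, routing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neohai.chaid import (
    CHAIDConfig,
    best_grouping,
    chi_square_independence,
    grow_tree,
    predict_node,
    stirling2,
)


class TestChiSquare:
    def test_perfect_association_statistic_equals_n(self):
        stat, p = chi_square_independence([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert p < 1e-9

    def test_identical_rows_give_zero(self):
        stat, p = chi_square_independence([[10, 5], [10, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_summed_formula_on_2x3_table(self):
        table = np.array([[10, 20, 30], [15, 10, 5]], dtype=float)
        expected = table.sum() * 0  # accumulate (O-E)^2/E by hand
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        E = row * col / table.sum()
        expected = ((table - E) ** 2 / E).sum()
        stat, _ = chi_square_independence(table)
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_collapsed_before_testing(self):
        stat, p = chi_square_independence([[20, 0], [0, 0], [0, 20]])
        assert stat == pytest.approx(40.0)


def all_partitions(items):
    """Every partition of a list (for brute-force grouping oracles)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


class TestBestGrouping:
    def test_binary_predictor_keeps_identity_with_multiplier_one(self):
        counts = pd.DataFrame([[30, 10], [5, 25]], index=["a", "b"], columns=[0, 1])
        result = best_grouping(counts)
        assert set(map(frozenset, result.groups)) == {frozenset("a"), frozenset("b")}
        assert result.multiplier == 1

    def test_single_category_signalled(self):
        counts = pd.DataFrame([[30, 10]], index=["a"], columns=[0, 1])
        assert best_grouping(counts) is None

    def test_categories_with_identical_rates_are_merged(self):
        counts = pd.DataFrame(
            [[40, 10], [40, 10], [5, 45]], index=["a", "b", "c"], columns=[0, 1]
        )
        result = best_grouping(counts)
        assert frozenset(["a", "b"]) in result.groups
        assert len(result.groups) == 2

    def test_matches_brute_force_over_all_partitions_of_three(self):
        """The exhaustive merge sequence finds the best adjusted p over all
        partitions of a 3-category predictor (merge path covers them here)."""
        counts = pd.DataFrame(
            [[40, 12], [38, 11], [6, 44]], index=["a", "b", "c"], columns=[0, 1]
        )
        result = best_grouping(counts)
        best_adj = np.inf
        for partition in all_partitions(list(counts.index)):
            if len(partition) < 2:
                continue
            table = np.vstack(
                [counts.loc[group].to_numpy().sum(axis=0) for group in partition]
            )
            _, p = chi_square_independence(table)
            adj = min(1.0, p * stirling2(3, len(partition)))
            best_adj = min(best_adj, adj)
        assert result.adjusted_p == pytest.approx(best_adj, rel=1e-12)

    def test_independent_outcome_has_large_adjusted_p(self):
        counts = pd.DataFrame(
            [[25, 25], [24, 26], [26, 24]], index=["a", "b", "c"], columns=[0, 1]
        )
        result = best_grouping(counts)
        assert result.adjusted_p > 0.05


def stirling_by_enumeration(n, k):
    count = 0
    for partition in all_partitions(list(range(n))):
        count += len(partition) == k
    return count


@pytest.mark.parametrize("n,k", [(3, 2), (4, 2), (4, 3), (5, 3)])
def test_stirling_numbers_match_enumeration(n, k):
    assert stirling2(n, k) == stirling_by_enumeration(n, k)


def two_predictor_frame(n=200, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = (a == 1) | ((b == 1) & (rng.uniform(size=n) < 0.8))
    data = pd.DataFrame({"a": a.astype(str), "b": b.astype(str)})
    return data, ["pos" if v else "neg" for v in y]


class TestGrowTree:
    def test_single_perfect_predictor_gives_two_pure_leaves(self):
        data = pd.DataFrame({"x": ["lo"] * 30 + ["hi"] * 30})
        outcome = ["neg"] * 30 + ["pos"] * 30
        tree = grow_tree(data, outcome, CHAIDConfig(min_parent_size=10, min_child_size=5))
        assert tree.split_predictor == "x"
        assert len(tree.children) == 2
        for child in tree.children:
            assert child.is_leaf
            assert len(child.class_counts) == 1

    def test_constant_outcome_gives_root_only_tree(self):
        data = pd.DataFrame({"x": ["a", "b"] * 20})
        tree = grow_tree(data, ["pos"] * 40)
        assert tree.is_leaf

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            grow_tree(pd.DataFrame({"x": []}), [])

    def test_counts_conserve_down_the_tree(self):
        data, outcome = two_predictor_frame(n=400, seed=1)
        tree = grow_tree(data, outcome, CHAIDConfig(min_parent_size=20, min_child_size=7))

        def check(node):
            if node.is_leaf:
                return
            for label, count in node.class_counts.items():
                assert count == sum(c.class_counts.get(label, 0) for c in node.children)
            for child in node.children:
                check(child)

        assert not tree.is_leaf
        check(tree)

    def test_matches_exhaustive_enumeration_on_two_binary_predictors(self):
        """Greedy most-significant-first growth equals the best tree found by
        enumerating both split orders on tie-free two-predictor data."""
        data, outcome = two_predictor_frame(n=300, seed=2)
        config = CHAIDConfig(min_parent_size=20, min_child_size=7, max_depth=2)
        tree = grow_tree(data, outcome, config)

        def root_adjusted_p(predictor):
            counts = pd.crosstab(data[predictor], pd.Series(outcome))
            return best_grouping(counts, config).adjusted_p

        best_first = min(data.columns, key=lambda c: (root_adjusted_p(c), c))
        assert tree.split_predictor == best_first

    def test_no_spurious_splits_on_permuted_outcomes(self):
        """With the outcome shuffled, the adjusted-p gate should refuse to
        split in roughly (1 - alpha)^2 of replicates (two predictors)."""
        data, outcome = two_predictor_frame(n=300, seed=3)
        rng = np.random.default_rng(42)
        outcome = np.array(outcome)
        splits = 0
        n_rep = 120
        for _ in range(n_rep):
            tree = grow_tree(data, rng.permutation(outcome), CHAIDConfig(max_depth=1))
            splits += not tree.is_leaf
        assert splits / n_rep <= 0.12  # ~2 * alpha with headroom for noise


class TestPredictNode:
    def test_routing_matches_hand_lookup_over_all_four_cells(self):
        data, outcome = two_predictor_frame(n=300, seed=4)
        tree = grow_tree(data, outcome, CHAIDConfig(min_parent_size=20, min_child_size=7))
        outcome = np.array(outcome)
        for a, b in itertools.product("01", repeat=2):
            leaf_id, proportions = predict_node(tree, {"a": a, "b": b})
            mask = (data["a"] == a).to_numpy()
            node = tree
            # hand routing: follow groupings from the root
            while not node.is_leaf:
                value = {"a": a, "b": b}[node.split_predictor]
                idx = next(
                    i for i, g in enumerate(node.category_grouping) if value in g
                )
                node = node.children[idx]
            assert node.node_id == leaf_id
            total = sum(node.class_counts.values())
            for label, count in node.class_counts.items():
                assert proportions[label] == pytest.approx(count / total)

    def test_root_only_tree_returns_overall_prevalence(self):
        data = pd.DataFrame({"x": ["a", "b"] * 20})
        tree = grow_tree(data, ["pos"] * 40)
        leaf_id, proportions = predict_node(tree, {"x": "a"})
        assert leaf_id == tree.node_id
        assert proportions == {"pos": 1.0}

    def test_pure_leaf_proportion_is_one(self):
        data = pd.DataFrame({"x": ["lo"] * 30 + ["hi"] * 30})
        outcome = ["neg"] * 30 + ["pos"] * 30
        tree = grow_tree(data, outcome, CHAIDConfig(min_parent_size=10, min_child_size=5))
        _, proportions = predict_node(tree, {"x": "hi"})
        assert proportions == {"pos": 1.0}

    def test_unseen_category_errors(self):
        data = pd.DataFrame({"x": ["lo"] * 30 + ["hi"] * 30})
        outcome = ["neg"] * 30 + ["pos"] * 30
        tree = grow_tree(data, outcome, CHAIDConfig(min_parent_size=10, min_child_size=5))
        with pytest.raises(ValueError):
            predict_node(tree, {"x": "mid"})


def test_synthetic_cohort_tree_recovers_the_two_variable_structure(large_cohort):
    """On a large calibrated cohort the tree splits first on the score band
    and, within the score-1 band, on the t24 CRP band."""
    from neohai.classification import classify_cohort, HAIClass
    from neohai.pipeline import _crp24_band, _score_band

    records, _ = large_cohort
    outcomes, _ = classify_cohort(records)
    truth = [o.any_hai for o in outcomes if isinstance(o, HAIClass)]
    feats = pd.DataFrame(
        {
            "neohop_t0_band": [_score_band(r, 10.0) for r in records],
            "crp_t24_band": [_crp24_band(r, 10.0) for r in records],
        }
    )
    tree = grow_tree(feats, ["any" if t else "no" for t in truth], CHAIDConfig())
    assert tree.split_predictor == "neohop_t0_band"
    score1_child = next(
        child
        for group, child in zip(tree.category_grouping, tree.children)
        if "1" in group
    )
    assert score1_child.split_predictor == "crp_t24_band"
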