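"""Exhaustive CHAID: chi-squared automatic interaction detection trees.

CHAID grows a decision tree over categorical predictors by, at each node,
(1) merging predictor categories that do not differ in outcome distribution
and (2) splitting on the predictor whose best category grouping is most
significantly associated with the outcome, with a Bonferroni adjustment for
the number of possible groupings.  The *exhaustive* variant does not stop
the merge sequence at the first non-significant pair: it merges all the way
down to two groups, evaluates every intermediate grouping, and keeps the one
with the smallest adjusted p-value.

For a nominal predictor with ``c`` original categories grouped into ``g``
compound categories, the Bonferroni multiplier is the number of ways to
partition ``c`` items into ``g`` non-empty groups — the Stirling number of
the second kind S(c, g).

Stopping rules: a node is not split if it is below ``min_parent_size``, at
``max_depth``, outcome-pure, or if no predictor achieves an adjusted
p <= ``alpha_split`` with all children at least ``min_child_size``.
The association test is the Pearson chi-square without continuity
correction (a likelihood-ratio variant is available behind a flag).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "CHAIDConfig",
    "CHAIDNode",
    "GroupingResult",
    "chi_square_independence",
    "best_grouping",
    "grow_tree",
    "predict_node",
    "stirling2",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CHAIDConfig:
    """Tree-growing parameters.

    ``alpha_merge`` is retained for interface compatibility but advisory in
    the exhaustive variant, which scans the whole merge sequence instead of
    stopping at the first non-significant merge.
    """

    alpha_split: float = 0.05
    alpha_merge: float = 0.05
    min_parent_size: int = 20
    min_child_size: int = 7
    max_depth: int = 3
    bonferroni: bool = True
    use_likelihood_ratio: bool = False

    def __post_init__(self):
        for name in ("alpha_split", "alpha_merge"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_parent_size < 1 or self.min_child_size < 1:
            raise ValueError("minimum node sizes must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class CHAIDNode:
    """One tree node; a leaf has no ``split_predictor`` and no children.

    ``category_grouping`` (internal nodes) is the partition of the split
    predictor's categories, aligned index-wise with ``children``.
    """

    node_id: int
    class_counts: dict[object, int]
    depth: int = 0
    split_predictor: str | None = None
    category_grouping: tuple[frozenset, ...] | None = None
    adjusted_p: float | None = None
    chi_square: float | None = None
    children: list["CHAIDNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.split_predictor is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        counts = ", ".join(f"{k}={v}" for k, v in sorted(self.class_counts.items(), key=str))
        lines = [f"{pad}node {self.node_id} [n={self.n}; {counts}]"]
        if not self.is_leaf:
            lines[-1] += (
                f" split on {self.split_predictor}"
                f" (chi2={self.chi_square:.3f}, adj p={self.adjusted_p:.4g})"
            )
            for group, child in zip(self.category_grouping, self.children):
                cats = "{" + ", ".join(sorted(map(str, group))) + "}"
                lines.append(f"{pad}  {self.split_predictor} in {cats}:")
                lines.append(child.to_text(indent + 2))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "n": self.n,
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
        }
        if not self.is_leaf:
            d.update(
                split_predictor=self.split_predictor,
                adjusted_p=self.adjusted_p,
                chi_square=self.chi_square,
                groups=[sorted(map(str, g)) for g in self.category_grouping],
                children=[c.to_dict() for c in self.children],
            )
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind: partitions of n items into k groups."""
    if n == k:
        return 1
    if k == 0 or k > n:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def chi_square_independence(
    table, use_likelihood_ratio: bool = False
) -> tuple[float, float]:
    """Pearson (or likelihood-ratio) chi-square test of independence.

    Zero-margin rows/columns are collapsed out before testing (logged);
    a table degenerate after collapsing yields statistic 0, p 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-way count table")
    if (arr < 0).any():
        raise ValueError("counts must be >= 0")
    row_keep = arr.sum(axis=1) > 0
    col_keep = arr.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.debug("collapsing zero-margin rows/columns before chi-square test")
        arr = arr[row_keep][:, col_keep]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 0.0, 1.0
    lambda_ = "log-likelihood" if use_likelihood_ratio else "pearson"
    res = chi2_contingency(arr, correction=False, lambda_=lambda_)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupingResult:
    """Best category grouping for one predictor at one node."""

    groups: tuple[frozenset, ...]
    chi_square: float
    p_value: float
    adjusted_p: float
    multiplier: int


def _grouped_table(
    counts: pd.DataFrame, groups: Sequence[frozenset]
) -> np.ndarray:
    return np.vstack([counts.loc[sorted(g, key=str)].to_numpy().sum(axis=0) for g in groups])


def best_grouping(
    counts: pd.DataFrame, config: CHAIDConfig = CHAIDConfig()
) -> GroupingResult | None:
    """Exhaustive-CHAID category grouping for one nominal predictor.

    ``counts`` is a categories x outcome-labels count table (e.g. from
    ``pd.crosstab``).  Starting from the identity partition, the least
    significantly different pair of (compound) categories is merged
    repeatedly down to two groups; every grouping along the sequence is
    scored against the outcome and the one with the smallest
    Bonferroni-adjusted p is returned.  Returns ``None`` for a
    single-category predictor (nothing to group or split on).
    """
    categories = list(counts.index)
    c = len(categories)
    if c < 2:
        return None
    use_lr = config.use_likelihood_ratio

    groups: list[frozenset] = [frozenset([cat]) for cat in categories]
    sequence: list[tuple[frozenset, ...]] = [tuple(groups)]
    while len(groups) > 2:
        # Merge the pair whose two count vectors differ least (largest p).
        best_pair, best_p = None, -1.0
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                table = _grouped_table(counts, [groups[i], groups[j]])
                _, p = chi_square_independence(table, use_lr)
                if p > best_p:
                    best_pair, best_p = (i, j), p
        i, j = best_pair
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
        sequence.append(tuple(groups))

    best: GroupingResult | None = None
    for grouping in sequence:
        g = len(grouping)
        table = _grouped_table(counts, grouping)
        stat, p = chi_square_independence(table, use_lr)
        multiplier = stirling2(c, g) if config.bonferroni else 1
        adjusted = min(1.0, p * multiplier)
        candidate = GroupingResult(
            groups=grouping,
            chi_square=stat,
            p_value=p,
            adjusted_p=adjusted,
            multiplier=multiplier,
        )
        if (
            best is None
            or (candidate.adjusted_p, -candidate.chi_square)
            < (best.adjusted_p, -best.chi_square)
        ):
            best = candidate
    return best


def grow_tree(
    data: pd.DataFrame,
    outcome: Sequence,
    config: CHAIDConfig = CHAIDConfig(),
) -> CHAIDNode:
    """Grow an exhaustive-CHAID tree over categorical predictors.

    ``data`` holds one categorical column per predictor; ``outcome`` is the
    class label per row (here: the any-HAI flag).  At each node the split
    predictor is the one whose best grouping has the smallest adjusted
    p <= ``alpha_split``; ties break by smaller raw p, then larger
    chi-square, then lexicographic predictor name.  A predictor is used at
    most once along any root-to-leaf path.
    """
    if len(data) == 0:
        raise ValueError("empty data")
    y = pd.Series(list(outcome), index=data.index, name="outcome")
    if len(y) != len(data):
        raise ValueError("outcome length must match data")
    counter = iter(range(10**9))
    return _grow(data, y, config, depth=0, counter=counter)


def _grow(data: pd.DataFrame, y: pd.Series, config: CHAIDConfig, depth: int, counter) -> CHAIDNode:
    node = CHAIDNode(
        node_id=next(counter),
        class_counts={k: int(v) for k, v in y.value_counts().sort_index(key=lambda i: i.map(str)).items()},
        depth=depth,
    )
    if (
        depth >= config.max_depth
        or len(data) < config.min_parent_size
        or y.nunique() < 2
    ):
        return node

    best_key = None
    best_choice: tuple[str, GroupingResult] | None = None
    for predictor in sorted(data.columns):
        counts = pd.crosstab(data[predictor], y)
        grouping = best_grouping(counts, config)
        if grouping is None or grouping.adjusted_p > config.alpha_split:
            continue
        sizes = [
            int(data[predictor].isin(group).sum()) for group in grouping.groups
        ]
        if min(sizes) < config.min_child_size:
            logger.debug(
                "predictor %s skipped: child of size %d < min_child_size",
                predictor,
                min(sizes),
            )
            continue
        key = (grouping.adjusted_p, grouping.p_value, -grouping.chi_square, predictor)
        if best_key is None or key < best_key:
            best_key, best_choice = key, (predictor, grouping)

    if best_choice is None:
        return node

    predictor, grouping = best_choice
    # Deterministic child order: by sorted category names within each group.
    ordered = sorted(grouping.groups, key=lambda g: sorted(map(str, g)))
    node.split_predictor = predictor
    node.category_grouping = tuple(ordered)
    node.adjusted_p = grouping.adjusted_p
    node.chi_square = grouping.chi_square
    remaining = data.drop(columns=[predictor])
    for group in ordered:
        mask = data[predictor].isin(group)
        child = _grow(remaining[mask], y[mask], config, depth + 1, counter)
        node.children.append(child)
    return node


def predict_node(tree: CHAIDNode, rec: dict) -> tuple[int, dict[object, float]]:
    """Route one record to a leaf; returns (leaf node_id, class proportions)."""
    node = tree
    while not node.is_leaf:
        value = rec[node.split_predictor]
        for group, child in zip(node.category_grouping, node.children):
            if value in group:
                node = child
                break
        else:
            raise ValueError(
                f"category {value!r} of predictor {node.split_predictor!r} "
                "not covered by any grouping"
            )
    n = node.n
    proportions = {k: v / n for k, v in node.class_counts.items()} if n else {}
    return node.node_id, proportions
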