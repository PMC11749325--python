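"""Distribution summaries and group-comparison tests for the LOT analysis.

Non-normally distributed quantities (antibiotic length of therapy, CRP) are
summarised as median and interquartile range and compared between groups with
the Mann-Whitney U test.  Quartiles default to the Tukey hinge convention
(the median of each half, including the middle observation when n is odd),
configurable to linear interpolation.

The Mann-Whitney implementation uses midranks for ties.  The exact two-sided
p-value is the null probability of a U at least as far from its mean as
observed, over all equally likely assignments of the pooled observations to
the two groups; it is computed by dynamic programming over the (doubled)
midranks, which is arithmetically identical to full enumeration but feasible
up to a few dozen observations.  The large-sample mode uses the normal
approximation with tie-corrected variance and a continuity correction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, wilcoxon

__all__ = [
    "GroupSummary",
    "MannWhitneyResult",
    "median_iqr",
    "mann_whitney_u",
    "lot_comparison",
    "plot_lot_comparison",
    "LOT_GROUPS",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float


def _median_sorted(xs: Sequence[float]) -> float:
    n = len(xs)
    mid = n // 2
    if n % 2:
        return float(xs[mid])
    return (xs[mid - 1] + xs[mid]) / 2.0


def median_iqr(values: Sequence[float], method: str = "tukey") -> GroupSummary:
    """Median and quartiles of a sample.

    ``method="tukey"`` uses Tukey hinges: the lower (upper) quartile is the
    median of the lower (upper) half of the sorted data, each half including
    the middle observation when n is odd.  ``method="linear"`` uses linear
    interpolation (numpy's default percentile).
    """
    if len(values) == 0:
        raise ValueError("median_iqr requires a non-empty sample")
    xs = sorted(float(v) for v in values)
    n = len(xs)
    med = _median_sorted(xs)
    if method == "tukey":
        q1 = _median_sorted(xs[: (n + 1) // 2])
        q3 = _median_sorted(xs[n // 2 :])
    elif method == "linear":
        q1, q3 = (float(q) for q in np.percentile(xs, [25, 75]))
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    arr = np.asarray(xs)
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return GroupSummary(n=n, median=med, q1=q1, q3=q3, mean=float(arr.mean()), sd=sd)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float
    mode: str


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def _exact_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by DP over subsets of the doubled midranks."""
    ranks2 = np.rint(2.0 * rankdata(pooled)).astype(int)
    n = len(ranks2)
    mu2 = n_a * (n - n_a) + n_a * (n_a + 1)  # 2*(mu_U + n_a(n_a+1)/2) = 2*mean rank sum
    dev_obs = abs(2.0 * u_obs + n_a * (n_a + 1) - mu2)
    # dp[k] maps doubled-rank-sum -> number of size-k subsets achieving it
    dp: list[Counter[int]] = [Counter() for _ in range(n_a + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(n_a - 1, -1, -1):
            if not dp[k]:
                continue
            target = dp[k + 1]
            for s, ways in dp[k].items():
                target[s + r] += ways
    total = math.comb(n, n_a)
    extreme = sum(
        ways for s, ways in dp[n_a].items() if abs(s - mu2) >= dev_obs - 1e-9
    )
    return min(1.0, extreme / total)


def _approx_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    n = len(pooled)
    n_b = n - n_a
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(0.0, abs(u_obs - mu) - 0.5) / math.sqrt(var)
    return float(2.0 * norm.sf(z))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "exact",
    max_exact_n: int = 40,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    ``mode="exact"`` enumerates the null distribution (combined n limited by
    ``max_exact_n``); ``mode="normal_approx"`` uses the tie-corrected normal
    approximation with continuity correction.  The reported U is the first
    sample's statistic.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    u = _u_statistic(a, b)
    if mode == "exact":
        if len(pooled) > max_exact_n:
            raise ValueError(
                f"exact mode limited to combined n <= {max_exact_n}; "
                "use mode='normal_approx'"
            )
        p = _exact_p(pooled, len(a), u)
    elif mode == "normal_approx":
        p = _approx_p(pooled, len(a), u)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MannWhitneyResult(u=u, p_value=p, mode=mode)


#: Strata reported by the LOT comparison, in output order.
LOT_GROUPS = ("overall", "no_hai", "any_hai", "proven", "presumed")


def _group_mask(labels: list[str | None], group: str) -> list[bool]:
    if group == "overall":
        return [lab is not None for lab in labels]
    if group == "no_hai":
        return [lab == "none" for lab in labels]
    if group == "any_hai":
        return [lab in ("proven", "presumed") for lab in labels]
    return [lab == group for lab in labels]


def lot_comparison(
    observed_lot: Sequence[float],
    theoretical_lot: Sequence[float | None],
    labels: Sequence[str | None],
    test: str = "mann_whitney",
    quartile_method: str = "tukey",
) -> pd.DataFrame:
    """Observed vs. theoretical antibiotic LOT per stratum.

    ``labels[i]`` is the episode's reference-standard label (``"proven"``,
    ``"presumed"``, ``"none"``; ``None`` for unclassifiable episodes) and
    ``theoretical_lot[i]`` is ``None`` where the tool was not evaluable; such
    episodes are excluded pairwise, with counts reported.  ``test`` selects
    ``"mann_whitney"`` (the default; approximate mode above combined n=40,
    exact below) or ``"wilcoxon"`` (paired signed-rank alternative).
    """
    if not (len(observed_lot) == len(theoretical_lot) == len(labels)):
        raise ValueError("input vectors must have equal length")
    if test not in ("mann_whitney", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    labels = list(labels)
    rows = []
    for group in LOT_GROUPS:
        mask = _group_mask(labels, group)
        obs_all = [o for o, m in zip(observed_lot, mask) if m]
        pairs = [
            (o, t)
            for o, t, m in zip(observed_lot, theoretical_lot, mask)
            if m and t is not None
        ]
        n_excluded = len(obs_all) - len(pairs)
        row: dict[str, object] = {
            "group": group,
            "n": len(pairs),
            "n_excluded": n_excluded,
        }
        if pairs:
            obs = [o for o, _ in pairs]
            theo = [t for _, t in pairs]
            for prefix, vec in (("observed", obs), ("theoretical", theo)):
                s = median_iqr(vec, quartile_method)
                row[f"{prefix}_median"] = s.median
                row[f"{prefix}_q1"] = s.q1
                row[f"{prefix}_q3"] = s.q3
            row["p_value"] = _compare_lot(obs, theo, test)
        else:
            for key in (
                "observed_median",
                "observed_q1",
                "observed_q3",
                "theoretical_median",
                "theoretical_q1",
                "theoretical_q3",
                "p_value",
            ):
                row[key] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def _compare_lot(obs: list[float], theo: list[float], test: str) -> float:
    if test == "wilcoxon":
        diffs = np.asarray(obs) - np.asarray(theo)
        if np.all(diffs == 0):
            return 1.0
        return float(wilcoxon(obs, theo, zero_method="wilcox").pvalue)
    mode = "exact" if len(obs) + len(theo) <= 40 else "normal_approx"
    return mann_whitney_u(obs, theo, mode=mode).p_value


def plot_lot_comparison(table: pd.DataFrame, path) -> None:
    """Grouped bar chart of observed vs. theoretical median LOT per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(table.index)
    x = np.arange(len(groups))
    width = 0.38
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - width / 2, table["observed_median"], width, label="Observed LOT")
    ax.bar(x + width / 2, table["theoretical_median"], width, label="Theoretical LOT")
    ax.set_xticks(x)
    ax.set_xticklabels(groups)
    ax.set_ylabel("Median antibiotic LOT (days)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
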