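"""Diagnostic accuracy against the any-HAI reference standard.

Builds confusion matrices from tri-state test calls (not-evaluable episodes
are excluded from the denominator, never coerced) and computes the standard
test-accuracy metrics:

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)                NPV = TN/(TN+FN)
    accuracy = (TP+TN)/n            NLR = (1-sens)/spec    PLR = sens/(1-spec)

Percentages are rounded half-away-from-zero to one decimal and likelihood
ratios to two decimals, computed on exact integer fractions so the printed
value is never a victim of binary floating point.  Metrics with a zero
denominator are reported as undefined (``None``), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .scoring import TriState

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "confusion_matrix",
    "diagnostic_metrics",
    "score_auc",
    "metric_ci",
    "metrics_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded: int = 0

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn", "n_excluded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(
    predictions: Sequence[TriState], truth: Sequence[bool]
) -> ConfusionMatrix:
    """Count TP/TN/FP/FN against the any-HAI reference standard.

    ``truth[i]`` is the any-HAI flag (must have no missing values); a
    not-evaluable prediction contributes only to ``n_excluded``.
    """
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    tp = tn = fp = fn = excluded = 0
    for pred, is_hai in zip(predictions, truth):
        if is_hai is None:
            raise ValueError("truth must have no missing values")
        if pred is TriState.NOT_EVALUABLE:
            excluded += 1
        elif pred is TriState.POSITIVE:
            tp, fp = (tp + 1, fp) if is_hai else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if is_hai else (fn, tn + 1)
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn, n_excluded=excluded)


def _round_ratio(num: int, den: int, places: int) -> float | None:
    """Round the exact rational num/den half-away-from-zero to `places`."""
    if den == 0:
        return None
    q = Decimal(num) / Decimal(den)
    return float(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Rounded display metrics (percentages to 1 dp, ratios to 2 dp).

    ``None`` marks an undefined metric (zero denominator; for the PLR also a
    perfectly specific test, where the ratio is infinite).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    nlr: float | None
    plr: float | None
    n_evaluable: int
    n_excluded: int


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """All test-accuracy metrics for one confusion matrix, exactly rounded."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    # NLR = (1-sens)/spec = fn*(tn+fp) / (tn*(tp+fn)); PLR analogously.
    nlr = _round_ratio(fn * (tn + fp), tn * (tp + fn), 2)
    plr = _round_ratio(tp * (tn + fp), fp * (tp + fn), 2) if fp > 0 else None
    return DiagnosticMetrics(
        sensitivity=_round_ratio(100 * tp, tp + fn, 1),
        specificity=_round_ratio(100 * tn, tn + fp, 1),
        ppv=_round_ratio(100 * tp, tp + fp, 1),
        npv=_round_ratio(100 * tn, tn + fn, 1),
        accuracy=_round_ratio(100 * (tp + tn), cm.n_evaluable, 1),
        nlr=nlr,
        plr=plr,
        n_evaluable=cm.n_evaluable,
        n_excluded=cm.n_excluded,
    )


def score_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC curve from rank sums.

    Equals the Mann-Whitney U statistic of scores between the diseased and
    non-diseased groups divided by n_pos * n_neg; ties contribute 1/2
    (midranks), which is the trapezoidal ROC convention.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


_CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}

_METRIC_COUNTS = {
    "sensitivity": lambda cm: (cm.tp, cm.tp + cm.fn),
    "specificity": lambda cm: (cm.tn, cm.tn + cm.fp),
    "ppv": lambda cm: (cm.tp, cm.tp + cm.fp),
    "npv": lambda cm: (cm.tn, cm.tn + cm.fn),
    "accuracy": lambda cm: (cm.tp + cm.tn, cm.n_evaluable),
}


def metric_ci(
    cm: ConfusionMatrix, method: str = "wilson", alpha: float = 0.05
) -> dict[str, tuple[float, float] | None]:
    """Two-sided binomial confidence intervals, as percentages.

    ``method`` is ``"wilson"`` or ``"clopper_pearson"``.  A metric with a
    zero denominator gets ``None``.
    """
    if method not in _CI_METHODS:
        raise ValueError(
            f"unsupported interval method {method!r}; expected one of {sorted(_CI_METHODS)}"
        )
    out: dict[str, tuple[float, float] | None] = {}
    for name, counts in _METRIC_COUNTS.items():
        k, n = counts(cm)
        if n == 0:
            out[name] = None
            continue
        lo, hi = proportion_confint(k, n, alpha=alpha, method=_CI_METHODS[method])
        out[name] = (100.0 * float(lo), 100.0 * float(hi))
    return out


_TABLE_ROWS = (
    "n",
    "true_positive",
    "true_negative",
    "false_positive",
    "false_negative",
    "sensitivity_pct",
    "specificity_pct",
    "negative_likelihood_ratio",
    "positive_predictive_value_pct",
    "negative_predictive_value_pct",
    "accuracy_pct",
)


def metrics_table(matrices: Mapping[str, ConfusionMatrix]) -> pd.DataFrame:
    """Diagnostic-accuracy table: tests as columns, counts and metrics as rows."""
    columns = {}
    for name, cm in matrices.items():
        m = diagnostic_metrics(cm)
        columns[name] = [
            cm.n_evaluable,
            cm.tp,
            cm.tn,
            cm.fp,
            cm.fn,
            m.sensitivity,
            m.specificity,
            m.nlr,
            m.ppv,
            m.npv,
            m.accuracy,
        ]
    return pd.DataFrame(columns, index=list(_TABLE_ROWS))
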