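"""The bedside antibiotic decision-making tool and theoretical length of therapy.

The tool applies the NeoHoP score at presentation (t0) and, when needed, the
point-of-care CRP 24 h later:

* score 0 — no antibiotics, no further investigations;
* score 1 — start antibiotics, then use the t24 CRP: below cutoff, stop after
  the first day; at or above cutoff, continue;
* score >= 2 — full antibiotic course per institutional guidelines.

The *theoretical* length of therapy (LOT) is the antibiotic course each
episode would have received under the tool: 0 days when the tool withholds
antibiotics, 1 day for the early-cessation branch, and the observed LOT when
the tool continues or gives a full course.  Episodes with score 1 and a
missing t24 CRP are not evaluable; they are counted and excluded pairwise
from observed-vs-theoretical comparisons (no imputation).
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass

from .episodes import EpisodeRecord
from .scoring import DEFAULT_CRP_CUTOFF, NeoHoPResult, compute_neohop

__all__ = [
    "Recommendation",
    "ToolOutcome",
    "recommend",
    "theoretical_lot",
    "apply_tool",
]

logger = logging.getLogger(__name__)


class Recommendation(enum.Enum):
    NO_ANTIBIOTICS = "no_antibiotics"
    START_THEN_STOP_24H = "start_then_stop_24h"
    START_THEN_CONTINUE = "start_then_continue"
    FULL_COURSE = "full_course"


@dataclass(frozen=True)
class ToolOutcome:
    recommendation: Recommendation
    theoretical_lot_days: float

    def __post_init__(self):
        if self.theoretical_lot_days < 0:
            raise ValueError("theoretical_lot_days must be >= 0")


def recommend(
    neohop_t0: NeoHoPResult,
    crp_t24: float | None,
    cutoff: float = DEFAULT_CRP_CUTOFF,
) -> Recommendation | None:
    """Tool recommendation for one episode; ``None`` when not evaluable.

    Not evaluable only in the score-1 branch with the t24 CRP missing.
    """
    if neohop_t0.total == 0:
        return Recommendation.NO_ANTIBIOTICS
    if neohop_t0.total >= 2:
        return Recommendation.FULL_COURSE
    if crp_t24 is None:
        return None
    if crp_t24 >= cutoff:
        return Recommendation.START_THEN_CONTINUE
    return Recommendation.START_THEN_STOP_24H


def theoretical_lot(recommendation: Recommendation, observed_lot_days: float) -> float:
    """Theoretical LOT in days for a recommendation.

    Withholding assigns 0 days, early cessation 1 day; continuation and a
    full course inherit the observed LOT (including observed 0 when the
    clinician never started antibiotics — there is no course to extend).
    """
    if observed_lot_days < 0:
        raise ValueError("observed_lot_days must be >= 0")
    if recommendation is Recommendation.NO_ANTIBIOTICS:
        return 0.0
    if recommendation is Recommendation.START_THEN_STOP_24H:
        return 1.0
    return float(observed_lot_days)


def apply_tool(
    records: list[EpisodeRecord],
    cutoff: float = DEFAULT_CRP_CUTOFF,
) -> tuple[list[ToolOutcome | None], int, dict[str, int]]:
    """Apply the tool to a cohort.

    Returns per-episode outcomes (``None`` where not evaluable: score 1 with
    missing t24 CRP, or t0 CRP missing so the score itself cannot be formed),
    the count of not-evaluable episodes, and branch counts.
    """
    outcomes: list[ToolOutcome | None] = []
    branch_counts: Counter[str] = Counter()
    n_not_evaluable = 0
    for rec in records:
        score = compute_neohop(rec, crp_cutoff=cutoff)
        rec_out: ToolOutcome | None = None
        if score is None:
            n_not_evaluable += 1
            branch_counts["not_evaluable_missing_t0"] += 1
            logger.info("episode %s: t0 CRP missing, score not evaluable", rec.episode_id)
        else:
            recommendation = recommend(score, rec.crp_t24, cutoff)
            if recommendation is None:
                n_not_evaluable += 1
                branch_counts["not_evaluable_score1_missing_t24"] += 1
                logger.info(
                    "episode %s: score 1 with t24 CRP missing, excluded", rec.episode_id
                )
            else:
                branch_counts[recommendation.value] += 1
                rec_out = ToolOutcome(
                    recommendation=recommendation,
                    theoretical_lot_days=theoretical_lot(
                        recommendation, rec.observed_lot_days
                    ),
                )
        outcomes.append(rec_out)
    return outcomes, n_not_evaluable, dict(branch_counts)
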