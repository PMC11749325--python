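"""NeoHoP score and point-of-care CRP test positivity.

The NeoHoP score sums five equally weighted binary items observed at the time
a suspected HAI episode is investigated (t0): capillary refill time > 3 s,
lethargy, abdominal distention, a central venous catheter in situ or removed
within the preceding 48 h, and CRP >= 10 mg/L.  A total of >= 2 is positive
(a rule-in test).

Five candidate tests are evaluated against the any-HAI reference standard:

* ``crp_t0`` — POC CRP at presentation >= cutoff;
* ``neohop_t0`` — NeoHoP score >= threshold;
* ``crp_t24`` — POC CRP 24 h later >= cutoff;
* ``crp_t0_and_t24_combined`` — positive if either time point >= cutoff;
* ``neohop_t0_and_crp_t24_combined`` — the decision-tree rule: score >= 2
  positive, score 0 negative, score 1 decided by the t24 CRP.

All threshold comparisons are inclusive (>=), with no tolerance band.  Tests
return a tri-state so that a missing measurement yields ``NOT_EVALUABLE``
rather than an arbitrary side of the cutoff.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .episodes import EpisodeRecord

__all__ = [
    "TriState",
    "TestSpec",
    "NeoHoPResult",
    "TEST_NAMES",
    "NEOHOP_COMPONENTS",
    "DEFAULT_CRP_CUTOFF",
    "DEFAULT_NEOHOP_THRESHOLD",
    "DEVICE_RANGE_MG_L",
    "clip_to_device_range",
    "crp_positive",
    "compute_neohop",
    "test_positivity",
]

#: Default POC CRP positivity cutoff, mg/L.
DEFAULT_CRP_CUTOFF = 10.0
#: Default NeoHoP rule-in threshold.
DEFAULT_NEOHOP_THRESHOLD = 2
#: Quantitative range of the POC CRP device, mg/L; values outside are censored.
DEVICE_RANGE_MG_L = (1.0, 200.0)

TEST_NAMES = (
    "crp_t0",
    "neohop_t0",
    "crp_t24",
    "crp_t0_and_t24_combined",
    "neohop_t0_and_crp_t24_combined",
)

NEOHOP_COMPONENTS = (
    "crt_gt_3s",
    "lethargy",
    "abdominal_distention",
    "cvc_in_situ_or_48h",
    "crp_ge_cutoff",
)


class TriState(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class TestSpec:
    """Configuration of one candidate test."""

    name: str
    crp_cutoff: float = DEFAULT_CRP_CUTOFF
    neohop_threshold: int = DEFAULT_NEOHOP_THRESHOLD

    def __post_init__(self):
        if self.name not in TEST_NAMES:
            raise ValueError(f"unknown test name {self.name!r}; expected one of {TEST_NAMES}")
        if not self.crp_cutoff > 0:
            raise ValueError("crp_cutoff must be > 0")
        if not 1 <= self.neohop_threshold <= 5:
            raise ValueError("neohop_threshold must be in 1..5")


@dataclass(frozen=True)
class NeoHoPResult:
    """Five named component flags, the total 0–5, and threshold positivity."""

    components: dict[str, bool]
    total: int
    positive: bool


def clip_to_device_range(value: float) -> float:
    """Censor a CRP concentration to the POC device's quantitative range."""
    lo, hi = DEVICE_RANGE_MG_L
    return min(max(value, lo), hi)


def crp_positive(value: float | None, cutoff: float = DEFAULT_CRP_CUTOFF) -> TriState:
    """Tri-state CRP thresholding: positive iff present and >= cutoff."""
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    if value is None:
        return TriState.NOT_EVALUABLE
    if value < 0:
        raise ValueError(f"CRP concentration must be >= 0, got {value}")
    return TriState.POSITIVE if value >= cutoff else TriState.NEGATIVE


def compute_neohop(
    rec: EpisodeRecord,
    crp_cutoff: float = DEFAULT_CRP_CUTOFF,
    threshold: int = DEFAULT_NEOHOP_THRESHOLD,
) -> NeoHoPResult | None:
    """Compute the NeoHoP score at t0.

    The CRP component uses the POC CRP at t0.  Returns ``None`` (score not
    evaluable) when ``crp_t0`` is absent — the score cannot be formed without
    its fifth item.
    """
    crp = crp_positive(rec.crp_t0, crp_cutoff)
    if crp is TriState.NOT_EVALUABLE:
        return None
    components = {
        "crt_gt_3s": rec.crt_gt_3s,
        "lethargy": rec.lethargy,
        "abdominal_distention": rec.abdominal_distention,
        "cvc_in_situ_or_48h": rec.cvc_in_situ_or_48h,
        "crp_ge_cutoff": crp is TriState.POSITIVE,
    }
    total = sum(components.values())
    return NeoHoPResult(components=components, total=total, positive=total >= threshold)


def _either_crp(rec: EpisodeRecord, cutoff: float) -> TriState:
    # Positive if any available time point >= cutoff; negative only when both
    # measurements are available and below; otherwise not evaluable.
    t0 = crp_positive(rec.crp_t0, cutoff)
    t24 = crp_positive(rec.crp_t24, cutoff)
    if TriState.POSITIVE in (t0, t24):
        return TriState.POSITIVE
    if t0 is TriState.NEGATIVE and t24 is TriState.NEGATIVE:
        return TriState.NEGATIVE
    return TriState.NOT_EVALUABLE


def _neohop_then_crp24(rec: EpisodeRecord, spec: TestSpec) -> TriState:
    score = compute_neohop(rec, spec.crp_cutoff, spec.neohop_threshold)
    if score is None:
        return TriState.NOT_EVALUABLE
    if score.total >= 2:
        return TriState.POSITIVE
    if score.total == 0:
        return TriState.NEGATIVE
    return crp_positive(rec.crp_t24, spec.crp_cutoff)


def test_positivity(rec: EpisodeRecord, spec: TestSpec) -> TriState:
    """Positivity of one candidate test for one episode."""
    if spec.name == "crp_t0":
        return crp_positive(rec.crp_t0, spec.crp_cutoff)
    if spec.name == "crp_t24":
        return crp_positive(rec.crp_t24, spec.crp_cutoff)
    if spec.name == "neohop_t0":
        score = compute_neohop(rec, spec.crp_cutoff, spec.neohop_threshold)
        if score is None:
            return TriState.NOT_EVALUABLE
        return TriState.POSITIVE if score.positive else TriState.NEGATIVE
    if spec.name == "crp_t0_and_t24_combined":
        return _either_crp(rec, spec.crp_cutoff)
    if spec.name == "neohop_t0_and_crp_t24_combined":
        return _neohop_then_crp24(rec, spec)
    raise ValueError(f"unknown test name {spec.name!r}")
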