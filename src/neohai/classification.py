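"""Reference-standard HAI classification: proven / presumed / no HAI.

Each suspected episode is labelled by the study case definitions:

* **proven HAI** — a blood culture isolating a known pathogen collected after
  72 h of admission with clinical signs of infection, or coagulase-negative
  staphylococci (CoNS) adjudicated as true infection;
* **presumed HAI** — a negative (non-probative) blood culture with a serum
  CRP >= 10 mg/L and antibiotics continued for >= 5 days;
* **no HAI** — short-lived symptoms, a negative culture, CRP < 10 mg/L, and
  antibiotics stopped within 48–72 h.

CoNS adjudication (adapted from the Stoll criteria): infection requires
either two positive cultures drawn 24–48 h apart, or a single positive
culture together with CRP >= 10 mg/L and clinical signs; anything else is
contamination.  A contaminated culture (CoNS-contamination or another CDC
contaminant) is *not probative* and behaves as negative for the presumed /
no-HAI branches.

"Any HAI" (proven or presumed) is the reference standard for the diagnostic
evaluation.  The three definitions do not literally partition every possible
field combination; episodes matching no branch yield an explicit
:class:`Unclassifiable` outcome carrying the conflicting fields — never a
silent default — and are excluded from accuracy denominators downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .episodes import BloodCultureResult, EpisodeRecord

__all__ = [
    "HAIClass",
    "Unclassifiable",
    "CRP_DEFINITION_CUTOFF",
    "classify_cons",
    "classify_hai",
    "classify_cohort",
]

logger = logging.getLogger(__name__)

#: Serum CRP cutoff (mg/L) used by the case definitions.
CRP_DEFINITION_CUTOFF = 10.0


@dataclass(frozen=True)
class HAIClass:
    """Reference-standard label with a machine-readable rationale."""

    label: str  # "proven" | "presumed" | "none"
    rationale: tuple[str, ...]

    def __post_init__(self):
        if self.label not in ("proven", "presumed", "none"):
            raise ValueError(f"invalid label {self.label!r}")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")

    @property
    def any_hai(self) -> bool:
        return self.label != "none"


@dataclass(frozen=True)
class Unclassifiable:
    """An episode matching none of the three case-definition branches."""

    conflicts: tuple[str, ...]

    @property
    def any_hai(self) -> None:
        return None


def classify_cons(
    culture: BloodCultureResult,
    crp: float | None,
    clinical_signs: bool,
    cutoff: float = CRP_DEFINITION_CUTOFF,
) -> str:
    """Adjudicate a CoNS-positive culture as ``"infection"`` or ``"contamination"``.

    Infection requires (i) paired positive cultures 24–48 h apart, or (ii) a
    single positive culture with CRP >= cutoff and clinical signs of
    infection.
    """
    if culture.organism_class != "cons":
        raise ValueError(
            f"classify_cons requires a CoNS culture, got {culture.organism_class!r}"
        )
    if culture.paired_cultures_24_48h_apart:
        return "infection"
    if (
        culture.n_positive_cultures == 1
        and crp is not None
        and crp >= cutoff
        and clinical_signs
    ):
        return "infection"
    return "contamination"


def _definition_crp(rec: EpisodeRecord, lab_crp: float | None) -> float | None:
    if lab_crp is not None:
        return lab_crp
    if rec.lab_crp is not None:
        return rec.lab_crp
    # The definitions cite the serum CRP; when no laboratory value is carried
    # the POC t0 measurement stands in for it.
    return rec.crp_t0


def classify_hai(
    rec: EpisodeRecord,
    lab_crp: float | None = None,
    cutoff: float = CRP_DEFINITION_CUTOFF,
) -> HAIClass | Unclassifiable:
    """Apply the three case definitions to one episode.

    ``lab_crp`` overrides the record's definition CRP; otherwise
    ``rec.lab_crp`` is used, falling back to ``rec.crp_t0``.  Deterministic:
    identical inputs always yield the identical outcome.
    """
    c = rec.culture
    crp = _definition_crp(rec, lab_crp)

    if c.organism_class == "pathogen":
        if c.collected_after_72h_admission and c.clinical_signs_present:
            return HAIClass(
                "proven",
                ("pathogen isolated after 72 h of admission with clinical signs",),
            )
        conflicts = ["pathogen culture"]
        if not c.collected_after_72h_admission:
            conflicts.append("not collected after 72 h of admission")
        if not c.clinical_signs_present:
            conflicts.append("no clinical signs of infection")
        return Unclassifiable(tuple(conflicts))

    if c.organism_class == "cons":
        verdict = classify_cons(c, crp, c.clinical_signs_present, cutoff)
        if verdict == "infection":
            reason = (
                "paired CoNS cultures 24-48 h apart"
                if c.paired_cultures_24_48h_apart
                else "single CoNS culture with CRP >= cutoff and clinical signs"
            )
            return HAIClass("proven", (reason,))
        # CoNS contamination: culture is not probative; fall through to the
        # culture-negative branches.
        culture_note = "CoNS adjudicated as contamination (culture not probative)"
    elif c.organism_class == "contaminant_other":
        culture_note = "contaminant organism (culture not probative)"
    else:
        culture_note = "negative blood culture"

    if crp is None:
        return Unclassifiable(
            (culture_note, "no definition CRP available (lab_crp and crp_t0 absent)")
        )
    if crp >= cutoff and rec.antibiotics_continued_ge_5d:
        return HAIClass(
            "presumed",
            (culture_note, f"CRP {crp:g} >= {cutoff:g} mg/L", "antibiotics continued >= 5 days"),
        )
    if crp < cutoff and rec.symptoms_short_lived and rec.abx_stopped_within_72h:
        return HAIClass(
            "none",
            (
                culture_note,
                f"CRP {crp:g} < {cutoff:g} mg/L",
                "short-lived symptoms",
                "antibiotics discontinued within 48-72 h",
            ),
        )

    conflicts = [culture_note, f"definition CRP {crp:g} mg/L"]
    if crp >= cutoff:
        conflicts.append("antibiotics not continued >= 5 days despite CRP >= cutoff")
    else:
        if not rec.symptoms_short_lived:
            conflicts.append("symptoms not short-lived despite CRP < cutoff")
        if not rec.abx_stopped_within_72h:
            conflicts.append("antibiotics not stopped within 72 h despite CRP < cutoff")
    return Unclassifiable(tuple(conflicts))


def classify_cohort(
    records,
    cutoff: float = CRP_DEFINITION_CUTOFF,
) -> tuple[list[HAIClass | Unclassifiable], int]:
    """Classify every record; returns (outcomes, n_unclassifiable).

    Unclassifiable episodes are logged (they are excluded from accuracy
    denominators by downstream consumers).
    """
    outcomes: list[HAIClass | Unclassifiable] = []
    n_unclassifiable = 0
    for rec in records:
        outcome = classify_hai(rec, cutoff=cutoff)
        if isinstance(outcome, Unclassifiable):
            n_unclassifiable += 1
            logger.warning(
                "episode %s unclassifiable: %s",
                rec.episode_id,
                "; ".join(outcome.conflicts),
            )
        outcomes.append(outcome)
    return outcomes, n_unclassifiable
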