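"""Episode-level domain types, CSV interchange, and validation.

One :class:`EpisodeRecord` describes a single suspected healthcare-associated
infection (HAI) episode in a hospitalised neonate: the clinical flags that
enter the NeoHoP infection-prediction score, point-of-care C-reactive protein
(CRP) measurements at presentation (t0) and 24 h later (t24), the blood
culture result, and the observed antibiotic course.

The canonical interchange format is a delimited text table (CSV by default)
with one header row naming the columns in :data:`CSV_COLUMNS`.  Absent CRP
values are written as empty cells and read back as ``None`` — never as zero —
so that a missing measurement can never silently satisfy or fail a threshold.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

__all__ = [
    "ORGANISM_CLASSES",
    "BloodCultureResult",
    "EpisodeRecord",
    "ValidationReport",
    "SchemaError",
    "RowParseError",
    "read_episodes",
    "write_episodes",
    "validate_episode",
    "CSV_COLUMNS",
]

#: Recognised blood-culture organism classes.  ``cons`` is coagulase-negative
#: staphylococci (requires adjudication); ``contaminant_other`` covers other
#: organisms on the CDC contaminant list.
ORGANISM_CLASSES = ("pathogen", "cons", "negative", "contaminant_other")

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class RowParseError(ValueError):
    """A cell in a data row could not be parsed; carries the 1-based row number."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


@dataclass(frozen=True)
class BloodCultureResult:
    """Blood-culture outcome for one episode.

    ``n_positive_cultures`` is zero exactly when ``organism_class`` is
    ``negative``; ``paired_cultures_24_48h_apart`` marks two positive cultures
    drawn 24–48 h apart (the first CoNS adjudication criterion).
    """

    organism_class: str
    n_positive_cultures: int = 0
    paired_cultures_24_48h_apart: bool = False
    collected_after_72h_admission: bool = False
    clinical_signs_present: bool = False


@dataclass(frozen=True)
class EpisodeRecord:
    """One suspected-HAI episode.

    CRP concentrations are in mg/L; ``None`` means not measured.  ``lab_crp``
    is the laboratory (serum) CRP used by the case definitions; when absent
    the classification falls back to the point-of-care ``crp_t0``.
    ``observed_lot_days`` is the antibiotic length of therapy: calendar days
    on any systemic antibiotic, irrespective of the number of agents; zero
    means no antibiotic was given for the episode.
    """

    episode_id: str
    subject_id: str
    postnatal_age_days: int
    crt_gt_3s: bool
    lethargy: bool
    abdominal_distention: bool
    cvc_in_situ_or_48h: bool
    crp_t0: float | None
    crp_t24: float | None
    culture: BloodCultureResult
    observed_lot_days: float
    antibiotics_continued_ge_5d: bool
    symptoms_short_lived: bool
    abx_stopped_within_72h: bool
    lab_crp: float | None = None


#: Required CSV columns, in canonical order.  ``lab_crp`` is optional on read.
CSV_COLUMNS = (
    "episode_id",
    "subject_id",
    "postnatal_age_days",
    "crt_gt_3s",
    "lethargy",
    "abdominal_distention",
    "cvc_in_situ_or_48h",
    "crp_t0",
    "crp_t24",
    "lab_crp",
    "organism_class",
    "n_positive_cultures",
    "paired_cultures_24_48h_apart",
    "collected_after_72h_admission",
    "clinical_signs_present",
    "observed_lot_days",
    "antibiotics_continued_ge_5d",
    "symptoms_short_lived",
    "abx_stopped_within_72h",
)

_OPTIONAL_COLUMNS = frozenset({"lab_crp"})

_FLAG_FIELDS = (
    "crt_gt_3s",
    "lethargy",
    "abdominal_distention",
    "cvc_in_situ_or_48h",
    "paired_cultures_24_48h_apart",
    "collected_after_72h_admission",
    "clinical_signs_present",
    "antibiotics_continued_ge_5d",
    "symptoms_short_lived",
    "abx_stopped_within_72h",
)


def _parse_flag(cell: str, column: str, row_number: int) -> bool:
    token = cell.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise RowParseError(row_number, f"cannot parse flag column {column!r} from {cell!r}")


def _parse_optional_float(cell: str, column: str, row_number: int) -> float | None:
    token = cell.strip()
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise RowParseError(
            row_number, f"cannot parse numeric column {column!r} from {cell!r}"
        ) from None


def _parse_float(cell: str, column: str, row_number: int) -> float:
    value = _parse_optional_float(cell, column, row_number)
    if value is None:
        raise RowParseError(row_number, f"column {column!r} must not be empty")
    return value


def _parse_int(cell: str, column: str, row_number: int) -> int:
    try:
        return int(cell.strip())
    except ValueError:
        raise RowParseError(
            row_number, f"cannot parse integer column {column!r} from {cell!r}"
        ) from None


def read_episodes(path, delimiter: str = ",") -> list[EpisodeRecord]:
    """Read episode records from a delimited text file.

    Raises :class:`SchemaError` naming the first missing required column and
    :class:`RowParseError` (with the 1-based data-row number) for unparseable
    cells.  Empty CRP cells become ``None``.
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError("input file has no header row")
        present = set(reader.fieldnames)
        for column in CSV_COLUMNS:
            if column not in present and column not in _OPTIONAL_COLUMNS:
                raise SchemaError(f"missing required column {column!r}")
        records = []
        for row_number, row in enumerate(reader, start=1):
            records.append(_parse_row(row, row_number))
    return records


def _parse_row(row: dict, row_number: int) -> EpisodeRecord:
    def cell(column: str) -> str:
        value = row.get(column)
        return "" if value is None else value

    organism = cell("organism_class").strip().lower()
    if organism not in ORGANISM_CLASSES:
        raise RowParseError(
            row_number,
            f"organism_class must be one of {ORGANISM_CLASSES}, got {organism!r}",
        )
    flags = {
        name: _parse_flag(cell(name), name, row_number) for name in _FLAG_FIELDS
    }
    culture = BloodCultureResult(
        organism_class=organism,
        n_positive_cultures=_parse_int(
            cell("n_positive_cultures"), "n_positive_cultures", row_number
        ),
        paired_cultures_24_48h_apart=flags["paired_cultures_24_48h_apart"],
        collected_after_72h_admission=flags["collected_after_72h_admission"],
        clinical_signs_present=flags["clinical_signs_present"],
    )
    return EpisodeRecord(
        episode_id=cell("episode_id").strip(),
        subject_id=cell("subject_id").strip(),
        postnatal_age_days=_parse_int(
            cell("postnatal_age_days"), "postnatal_age_days", row_number
        ),
        crt_gt_3s=flags["crt_gt_3s"],
        lethargy=flags["lethargy"],
        abdominal_distention=flags["abdominal_distention"],
        cvc_in_situ_or_48h=flags["cvc_in_situ_or_48h"],
        crp_t0=_parse_optional_float(cell("crp_t0"), "crp_t0", row_number),
        crp_t24=_parse_optional_float(cell("crp_t24"), "crp_t24", row_number),
        lab_crp=_parse_optional_float(cell("lab_crp"), "lab_crp", row_number),
        culture=culture,
        observed_lot_days=_parse_float(
            cell("observed_lot_days"), "observed_lot_days", row_number
        ),
        antibiotics_continued_ge_5d=flags["antibiotics_continued_ge_5d"],
        symptoms_short_lived=flags["symptoms_short_lived"],
        abx_stopped_within_72h=flags["abx_stopped_within_72h"],
    )


def _format_optional(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def record_to_row(rec: EpisodeRecord) -> dict[str, str]:
    """Flatten a record into the canonical CSV row (strings)."""
    c = rec.culture
    return {
        "episode_id": rec.episode_id,
        "subject_id": rec.subject_id,
        "postnatal_age_days": str(rec.postnatal_age_days),
        "crt_gt_3s": str(int(rec.crt_gt_3s)),
        "lethargy": str(int(rec.lethargy)),
        "abdominal_distention": str(int(rec.abdominal_distention)),
        "cvc_in_situ_or_48h": str(int(rec.cvc_in_situ_or_48h)),
        "crp_t0": _format_optional(rec.crp_t0),
        "crp_t24": _format_optional(rec.crp_t24),
        "lab_crp": _format_optional(rec.lab_crp),
        "organism_class": c.organism_class,
        "n_positive_cultures": str(c.n_positive_cultures),
        "paired_cultures_24_48h_apart": str(int(c.paired_cultures_24_48h_apart)),
        "collected_after_72h_admission": str(int(c.collected_after_72h_admission)),
        "clinical_signs_present": str(int(c.clinical_signs_present)),
        "observed_lot_days": repr(float(rec.observed_lot_days)),
        "antibiotics_continued_ge_5d": str(int(rec.antibiotics_continued_ge_5d)),
        "symptoms_short_lived": str(int(rec.symptoms_short_lived)),
        "abx_stopped_within_72h": str(int(rec.abx_stopped_within_72h)),
    }


def write_episodes(records: Iterable[EpisodeRecord], path, delimiter: str = ",") -> None:
    """Write records to a delimited file; ``read_episodes`` round-trips it."""
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=CSV_COLUMNS, delimiter=delimiter)
        writer.writeheader()
        for rec in records:
            writer.writerow(record_to_row(rec))


@dataclass
class ValidationReport:
    """Outcome of validating one record; violations are data, not exceptions."""

    episode_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            {"episode_id": self.episode_id, "ok": self.ok, "violations": self.violations}
        )


def validate_episode(rec: EpisodeRecord) -> ValidationReport:
    """Check every type invariant; returns a report enumerating violations."""
    v: list[str] = []
    if rec.observed_lot_days < 0:
        v.append("observed_lot_days: must be >= 0")
    for name in ("crp_t0", "crp_t24", "lab_crp"):
        value = getattr(rec, name)
        if value is not None and value < 0:
            v.append(f"{name}: concentration must be >= 0 when present")
    if rec.antibiotics_continued_ge_5d and rec.observed_lot_days < 5:
        v.append(
            "antibiotics_continued_ge_5d: implies observed_lot_days >= 5 "
            f"(got {rec.observed_lot_days})"
        )
    if rec.postnatal_age_days < 0:
        v.append("postnatal_age_days: must be >= 0")
    c = rec.culture
    if c.organism_class not in ORGANISM_CLASSES:
        v.append(f"organism_class: unknown class {c.organism_class!r}")
    if c.n_positive_cultures < 0:
        v.append("n_positive_cultures: must be >= 0")
    if (c.n_positive_cultures == 0) != (c.organism_class == "negative"):
        v.append(
            "n_positive_cultures: must be 0 exactly when organism_class is 'negative'"
        )
    if c.paired_cultures_24_48h_apart and c.n_positive_cultures < 2:
        v.append("paired_cultures_24_48h_apart: implies n_positive_cultures >= 2")
    return ValidationReport(episode_id=rec.episode_id, violations=v)
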