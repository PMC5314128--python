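"""Data model and I/O for patients, prescriptions and diagnosis events.

The package consumes three flat CSV files::

    patients.csv       patient_id, date_of_birth, date_of_death, sex
    prescriptions.csv  patient_id, drug_class, start_date, end_date,
                       daily_dose_mg, quantity_mg
    events.csv         patient_id, event_date, icd9_code, same_day_order

Dates are ISO-8601 (YYYY-MM-DD) and inclusive; missing optional values are
empty fields.  Prescriptions are converted to non-overlapping
:class:`ExposureEpisode` intervals: a recorded end date wins, otherwise the
duration is derived from daily dose and dispensed quantity, otherwise the
configured median prescription length is imputed.  Overlapping or abutting
prescriptions merge into a single episode (continuous supply is treated as
continuous exposure); a gap of one day or more starts a new episode.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A CSV file does not carry the documented header."""


class DrugClass(str, enum.Enum):
    MPH = "MPH"
    ATOMOXETINE = "atomoxetine"
    ANTIDEPRESSANT = "antidepressant"
    ANTIPSYCHOTIC = "antipsychotic"
    OTHER = "other"


class CodeGroup(str, enum.Enum):
    PSYCHOSIS = "psychosis"
    HALLUCINATION = "hallucination"
    OTHER_PSYCHOTIC = "other_psychotic"
    SUBSTANCE = "substance"
    NON_OUTCOME = "non_outcome"


#: outcome groups eligible to be an incident psychotic event
OUTCOME_GROUPS = frozenset(
    {CodeGroup.PSYCHOSIS, CodeGroup.HALLUCINATION, CodeGroup.OTHER_PSYCHOTIC}
)


class SameDayOrder(str, enum.Enum):
    BEFORE_TREATMENT = "before_treatment"
    AFTER_TREATMENT = "after_treatment"
    UNKNOWN = "unknown"


class DurationSource(str, enum.Enum):
    RECORDED = "recorded"
    DOSE_QUANTITY = "dose_quantity"
    IMPUTED_MEDIAN = "imputed_median"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    date_of_birth: date
    date_of_death: date | None = None
    sex: Sex = Sex.UNKNOWN


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_class: DrugClass
    start_date: date
    end_date: date | None = None
    daily_dose_mg: float | None = None
    quantity_mg: float | None = None


@dataclass(frozen=True)
class EventRecord:
    patient_id: str
    event_date: date
    code: str
    code_group: CodeGroup
    same_day_order: SameDayOrder = SameDayOrder.UNKNOWN


@dataclass(frozen=True)
class ExposureEpisode:
    """A contiguous on-medication interval (inclusive dates)."""

    patient_id: str
    start_date: date
    end_date: date
    duration_source: DurationSource

    @property
    def duration_days(self) -> int:
        return self.end_date.toordinal() - self.start_date.toordinal() + 1


# ---------------------------------------------------------------------------
# ICD-9-CM code map


#: exact ICD-9-CM codes for psychotic disorders used as the primary outcome
DEFAULT_PSYCHOSIS_CODES = ("298.0", "298.1", "298.3", "298.8", "298.9")
#: hallucinations
DEFAULT_HALLUCINATION_CODES = ("780.1",)
#: substance misuse / dependence chapters (integer code range, inclusive)
DEFAULT_SUBSTANCE_RANGES = ((303, 305),)


class CodeMap:
    """Deterministic mapping from ICD-9-CM code strings to code groups.

    Exact code matches take precedence; otherwise the integer part of the
    code is looked up in the configured ranges; anything else is
    ``non_outcome``.
    """

    def __init__(
        self,
        exact: Mapping[str, CodeGroup] | None = None,
        ranges: Sequence[tuple[int, int, CodeGroup]] | None = None,
    ):
        if exact is None and ranges is None:
            exact = {c: CodeGroup.PSYCHOSIS for c in DEFAULT_PSYCHOSIS_CODES}
            exact.update({c: CodeGroup.HALLUCINATION for c in DEFAULT_HALLUCINATION_CODES})
            ranges = [(lo, hi, CodeGroup.SUBSTANCE) for lo, hi in DEFAULT_SUBSTANCE_RANGES]
        self.exact = dict(exact or {})
        self.ranges = list(ranges or [])

    def classify(self, code: str) -> CodeGroup:
        code = code.strip()
        if code in self.exact:
            return self.exact[code]
        head = code.split(".", 1)[0]
        if head.isdigit():
            num = int(head)
            for lo, hi, group in self.ranges:
                if lo <= num <= hi:
                    return group
        return CodeGroup.NON_OUTCOME

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeMap":
        """Load a map of the form ``{group: {codes: [...], ranges: [[lo, hi]]}}``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        exact: dict[str, CodeGroup] = {}
        ranges: list[tuple[int, int, CodeGroup]] = []
        for group_name, entry in raw.items():
            group = CodeGroup(group_name)
            for code in (entry or {}).get("codes", []) or []:
                exact[str(code)] = group
            for lo, hi in (entry or {}).get("ranges", []) or []:
                ranges.append((int(lo), int(hi), group))
        return cls(exact, ranges)


# ---------------------------------------------------------------------------
# CSV readers


@dataclass
class RowIssue:
    row: int  # 1-based data row number (header not counted)
    message: str


@dataclass
class ParseResult:
    """Parsed records plus per-row issues for malformed input."""

    records: list
    errors: list[RowIssue]

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


PATIENT_COLUMNS = ["patient_id", "date_of_birth", "date_of_death", "sex"]
PRESCRIPTION_COLUMNS = [
    "patient_id",
    "drug_class",
    "start_date",
    "end_date",
    "daily_dose_mg",
    "quantity_mg",
]
EVENT_COLUMNS = ["patient_id", "event_date", "icd9_code", "same_day_order"]


def _read_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _parse_date(text: str, field: str) -> date | None:
    text = text.strip()
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"unparseable {field} {text!r}") from exc


def _parse_float(text: str, field: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable {field} {text!r}") from exc
    if value <= 0:
        raise ValueError(f"{field} must be positive, got {value}")
    return value


def read_patients(path: str | Path) -> ParseResult:
    frame = _read_frame(path, PATIENT_COLUMNS)
    records: list[PatientRecord] = []
    errors: list[RowIssue] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            pid = row.patient_id.strip()
            if not pid:
                raise ValueError("empty patient_id")
            if pid in seen:
                raise ValueError(f"duplicate patient_id {pid!r}")
            dob = _parse_date(row.date_of_birth, "date_of_birth")
            if dob is None:
                raise ValueError("missing date_of_birth")
            dod = _parse_date(row.date_of_death, "date_of_death")
            if dod is not None and dod < dob:
                raise ValueError(f"patient {pid}: death {dod} precedes birth {dob}")
            sex = Sex(row.sex.strip()) if row.sex.strip() else Sex.UNKNOWN
            records.append(PatientRecord(pid, dob, dod, sex))
            seen.add(pid)
        except ValueError as exc:
            errors.append(RowIssue(i, str(exc)))
    if errors:
        log.warning("%s: skipped %d malformed row(s)", path, len(errors))
    return ParseResult(records, errors)


def read_prescriptions(path: str | Path) -> ParseResult:
    frame = _read_frame(path, PRESCRIPTION_COLUMNS)
    records: list[PrescriptionRecord] = []
    errors: list[RowIssue] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            pid = row.patient_id.strip()
            if not pid:
                raise ValueError("empty patient_id")
            drug = DrugClass(row.drug_class.strip())
            start = _parse_date(row.start_date, "start_date")
            if start is None:
                raise ValueError("missing start_date")
            end = _parse_date(row.end_date, "end_date")
            if end is not None and end < start:
                raise ValueError(f"end_date {end} precedes start_date {start}")
            dose = _parse_float(row.daily_dose_mg, "daily_dose_mg")
            qty = _parse_float(row.quantity_mg, "quantity_mg")
            records.append(PrescriptionRecord(pid, drug, start, end, dose, qty))
        except ValueError as exc:
            errors.append(RowIssue(i, str(exc)))
    if errors:
        log.warning("%s: skipped %d malformed row(s)", path, len(errors))
    return ParseResult(records, errors)


def read_events(path: str | Path, code_map: CodeMap | None = None) -> ParseResult:
    code_map = code_map or CodeMap()
    frame = _read_frame(path, EVENT_COLUMNS)
    records: list[EventRecord] = []
    errors: list[RowIssue] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            pid = row.patient_id.strip()
            if not pid:
                raise ValueError("empty patient_id")
            when = _parse_date(row.event_date, "event_date")
            if when is None:
                raise ValueError("missing event_date")
            code = row.icd9_code.strip()
            if not code:
                raise ValueError("missing icd9_code")
            order_text = row.same_day_order.strip()
            order = SameDayOrder(order_text) if order_text else SameDayOrder.UNKNOWN
            records.append(EventRecord(pid, when, code, code_map.classify(code), order))
        except ValueError as exc:
            errors.append(RowIssue(i, str(exc)))
    if errors:
        log.warning("%s: skipped %d malformed row(s)", path, len(errors))
    return ParseResult(records, errors)


# ---------------------------------------------------------------------------
# CSV writers (canonical form: ISO dates, integral numbers without decimals)


def _fmt_date(value: date | None) -> str:
    return value.isoformat() if value is not None else ""


def _fmt_num(value: float | None) -> str:
    if value is None:
        return ""
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def write_patients(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        (r.patient_id, _fmt_date(r.date_of_birth), _fmt_date(r.date_of_death), r.sex.value)
        for r in records
    ]
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def write_prescriptions(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    rows = [
        (
            r.patient_id,
            r.drug_class.value,
            _fmt_date(r.start_date),
            _fmt_date(r.end_date),
            _fmt_num(r.daily_dose_mg),
            _fmt_num(r.quantity_mg),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS).to_csv(path, index=False)


def write_events(records: Iterable[EventRecord], path: str | Path) -> None:
    rows = [
        (r.patient_id, _fmt_date(r.event_date), r.code, r.same_day_order.value)
        for r in records
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exposure episodes


def episode_duration(
    rx: PrescriptionRecord, median_days: int = 70
) -> tuple[int, DurationSource]:
    """Days of exposure implied by one prescription and where they came from.

    Preference order: recorded end date, then dispensed quantity divided by
    daily dose, then the configured median prescription length.
    """
    if median_days <= 0:
        raise ValueError("median_days must be positive")
    if rx.end_date is not None:
        days = rx.end_date.toordinal() - rx.start_date.toordinal() + 1
        if days <= 0:
            raise ValueError(
                f"prescription for {rx.patient_id} has non-positive recorded duration"
            )
        return days, DurationSource.RECORDED
    if rx.daily_dose_mg is not None and rx.quantity_mg is not None:
        days = round(rx.quantity_mg / rx.daily_dose_mg)
        if days < 1:
            log.warning(
                "patient %s: dose/quantity duration < 1 day, clamped to 1", rx.patient_id
            )
            days = 1
        return int(days), DurationSource.DOSE_QUANTITY
    return int(median_days), DurationSource.IMPUTED_MEDIAN


_SOURCE_RELIABILITY = {
    DurationSource.RECORDED: 0,
    DurationSource.DOSE_QUANTITY: 1,
    DurationSource.IMPUTED_MEDIAN: 2,
}


def build_episodes(
    rxs: Sequence[PrescriptionRecord], median_days: int = 70
) -> list[ExposureEpisode]:
    """Merge one patient's MPH prescriptions into sorted exposure episodes.

    Overlapping or abutting prescriptions (next start at most one day after
    the previous end) merge; a gap of one or more uncovered days separates
    episodes.  Duplicate identical prescription rows are dropped with a
    logged count.  A merged episode is labelled with the least reliable
    duration source among its constituents.
    """
    if not rxs:
        return []
    pids = {r.patient_id for r in rxs}
    if len(pids) != 1:
        raise ValueError(f"build_episodes expects one patient, got {sorted(pids)}")
    if any(r.drug_class != DrugClass.MPH for r in rxs):
        raise ValueError("build_episodes expects MPH prescriptions only")

    unique = list(dict.fromkeys(rxs))
    if len(unique) < len(rxs):
        log.info(
            "patient %s: dropped %d duplicate prescription row(s)",
            rxs[0].patient_id,
            len(rxs) - len(unique),
        )

    spans: list[tuple[int, int, DurationSource]] = []
    for rx in unique:
        days, source = episode_duration(rx, median_days)
        start = rx.start_date.toordinal()
        spans.append((start, start + days - 1, source))
    spans.sort(key=lambda s: (s[0], s[1]))

    merged: list[list] = []
    for start, end, source in spans:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
            if _SOURCE_RELIABILITY[source] > _SOURCE_RELIABILITY[merged[-1][2]]:
                merged[-1][2] = source
        else:
            merged.append([start, end, source])

    pid = unique[0].patient_id
    return [
        ExposureEpisode(pid, date.fromordinal(s), date.fromordinal(e), src)
        for s, e, src in merged
    ]


def duration_source_counts(
    rxs: Iterable[PrescriptionRecord], median_days: int = 70
) -> dict[str, int]:
    """How many prescriptions used each duration-derivation path."""
    counts = {source.value: 0 for source in DurationSource}
    for rx in rxs:
        _, source = episode_duration(rx, median_days)
        counts[source.value] += 1
    return counts
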