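"""In-memory cohort container grouping the three record streams by patient."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .records import (
    CodeMap,
    EventRecord,
    PatientRecord,
    PrescriptionRecord,
    read_events,
    read_patients,
    read_prescriptions,
)


@dataclass
class SCCSData:
    """Patients, prescriptions and diagnosis events for one cohort."""

    patients: list[PatientRecord]
    prescriptions: list[PrescriptionRecord]
    events: list[EventRecord]
    code_map: CodeMap = field(default_factory=CodeMap)
    read_issues: dict = field(default_factory=dict)

    def __post_init__(self):
        self._rx_by_patient: dict[str, list[PrescriptionRecord]] = {}
        for rx in self.prescriptions:
            self._rx_by_patient.setdefault(rx.patient_id, []).append(rx)
        self._events_by_patient: dict[str, list[EventRecord]] = {}
        for ev in self.events:
            self._events_by_patient.setdefault(ev.patient_id, []).append(ev)
        for evs in self._events_by_patient.values():
            evs.sort(key=lambda e: (e.event_date, e.code))

    def prescriptions_for(self, patient_id: str) -> list[PrescriptionRecord]:
        return self._rx_by_patient.get(patient_id, [])

    def events_for(self, patient_id: str) -> list[EventRecord]:
        return self._events_by_patient.get(patient_id, [])

    @classmethod
    def from_csv(
        cls,
        patients_path: str | Path,
        prescriptions_path: str | Path,
        events_path: str | Path,
        code_map: CodeMap | str | Path | None = None,
    ) -> "SCCSData":
        if code_map is None:
            code_map = CodeMap()
        elif not isinstance(code_map, CodeMap):
            code_map = CodeMap.from_yaml(code_map)
        patients = read_patients(patients_path)
        prescriptions = read_prescriptions(prescriptions_path)
        events = read_events(events_path, code_map)
        issues = {
            "patients": patients.errors,
            "prescriptions": prescriptions.errors,
            "events": events.errors,
        }
        return cls(patients.records, prescriptions.records, events.records, code_map, issues)
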