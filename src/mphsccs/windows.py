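"""Per-patient observation windows under the study entry, exit and censoring rules.

Observation starts at the study opening (2001-01-01 by default) or the sixth
birthday, whichever is later, and ends at the study close (2014-12-31), the
day before the twentieth birthday (so that age 19 is fully included), the day
before the first atomoxetine prescription, or the registered date of death,
whichever is earliest.  Sensitivity variants may additionally censor at the
first antidepressant/antipsychotic prescription, or delay entry to the first
ADHD diagnosis / first MPH prescription.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

from ._calendar import anniversary
from .records import DrugClass, EventRecord, OUTCOME_GROUPS, PatientRecord


class EndReason(str, enum.Enum):
    STUDY_END = "study_end"
    TWENTIETH_BIRTHDAY = "twentieth_birthday"
    ATOMOXETINE = "atomoxetine"
    DEATH = "death"
    PSYCHOTROPIC_CENSOR = "psychotropic_censor"
    NONE_ELIGIBLE = "none_eligible"


@dataclass(frozen=True)
class ObservationWindow:
    patient_id: str
    start_date: date
    end_date: date
    end_reason: EndReason

    @property
    def eligible(self) -> bool:
        return self.end_reason != EndReason.NONE_ELIGIBLE

    @property
    def length_days(self) -> int:
        return self.end_date.toordinal() - self.start_date.toordinal() + 1


def build_window(
    patient: PatientRecord,
    censor_dates: Mapping[DrugClass, date] | None = None,
    scenario=None,
    start_override: date | None = None,
) -> ObservationWindow:
    """Observation window for one patient, or an ineligible marker.

    ``censor_dates`` maps a drug class to the first prescription date of that
    class for this patient.  ``scenario`` is read for ``study_start``,
    ``study_end`` and ``censor_psychotropics`` (duck-typed so any config
    object with those attributes works).  ``start_override`` implements the
    delayed-entry sensitivity rule; it can only move the start later.
    """
    censor_dates = censor_dates or {}
    study_start = getattr(scenario, "study_start", None) or date(2001, 1, 1)
    study_end = getattr(scenario, "study_end", None) or date(2014, 12, 31)
    censor_psy = bool(getattr(scenario, "censor_psychotropics", False))

    start_ord = max(study_start.toordinal(), anniversary(patient.date_of_birth, 6))
    if start_override is not None:
        start_ord = max(start_ord, start_override.toordinal())

    # censoring at a drug ends the window the day before first receipt
    candidates: list[tuple[int, EndReason]] = [
        (study_end.toordinal(), EndReason.STUDY_END),
        (anniversary(patient.date_of_birth, 20) - 1, EndReason.TWENTIETH_BIRTHDAY),
    ]
    if patient.date_of_death is not None:
        candidates.append((patient.date_of_death.toordinal(), EndReason.DEATH))
    atx = censor_dates.get(DrugClass.ATOMOXETINE)
    if atx is not None:
        candidates.append((atx.toordinal() - 1, EndReason.ATOMOXETINE))
    if censor_psy:
        psy_dates = [
            censor_dates[d]
            for d in (DrugClass.ANTIDEPRESSANT, DrugClass.ANTIPSYCHOTIC)
            if d in censor_dates
        ]
        if psy_dates:
            candidates.append((min(psy_dates).toordinal() - 1, EndReason.PSYCHOTROPIC_CENSOR))

    end_ord, reason = min(candidates, key=lambda c: (c[0], _REASON_PRIORITY[c[1]]))
    if start_ord > end_ord:
        return ObservationWindow(
            patient.patient_id,
            date.fromordinal(start_ord),
            date.fromordinal(start_ord),
            EndReason.NONE_ELIGIBLE,
        )
    return ObservationWindow(
        patient.patient_id, date.fromordinal(start_ord), date.fromordinal(end_ord), reason
    )


_REASON_PRIORITY = {
    EndReason.STUDY_END: 0,
    EndReason.TWENTIETH_BIRTHDAY: 1,
    EndReason.ATOMOXETINE: 2,
    EndReason.DEATH: 3,
    EndReason.PSYCHOTROPIC_CENSOR: 4,
}

#: same-day tie-break priority between outcome groups
_GROUP_PRIORITY = {"psychosis": 0, "hallucination": 1, "other_psychotic": 2}


def select_incident_event(
    events: Sequence[EventRecord],
    window: ObservationWindow,
    scenario=None,
) -> tuple[EventRecord | None, str]:
    """Pick the incident (first in-window) outcome event.

    Returns ``(event, "case")``, ``(None, "excluded_prior_event")`` when any
    qualifying outcome event precedes the window start (such patients are
    excluded entirely), or ``(None, "no_event")``.  Same-day ties resolve by
    group priority psychosis > hallucination > other psychotic, then lexical
    code order.  ``scenario.outcomes`` restricts the qualifying groups (for
    example removing hallucinations).
    """
    outcome_names = getattr(scenario, "outcomes", None)
    if outcome_names is None:
        qualifying = {g.value for g in OUTCOME_GROUPS}
    else:
        qualifying = {str(o) for o in outcome_names}

    eligible = [e for e in events if e.code_group.value in qualifying]
    if any(e.event_date < window.start_date for e in eligible):
        return None, "excluded_prior_event"
    in_window = [
        e for e in eligible if window.start_date <= e.event_date <= window.end_date
    ]
    if not in_window:
        return None, "no_event"
    chosen = min(
        in_window,
        key=lambda e: (e.event_date, _GROUP_PRIORITY.get(e.code_group.value, 9), e.code),
    )
    return chosen, "case"
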