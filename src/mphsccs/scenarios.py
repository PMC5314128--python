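"""Declarative scenario configuration and batch execution.

The primary analysis and the sensitivity battery are all expressed as
:class:`ScenarioConfig` values; :func:`run_scenario` executes the full
pipeline (episodes -> windows -> incident event -> segmentation -> fit) for
one configuration and :func:`render_report` lays the results out in the
familiar IRR | 95% CI | P-value block format, one block per scenario.

Built-in battery (24 configurations): the primary analysis without a
pre-exposure window, the primary analysis with the 90-day pre-exposure
window, and the sensitivity variants — episode extension by 1-10 weeks,
6-month age bands, the >10-week exposure subset, antidepressant/antipsychotic
censoring, substance-misuse exclusion (ICD-9-CM 303-305), hallucination
removal (780.1), first-day event removal, 7/14/21-day washout, delayed
entry, and 60/30-day pre-exposure windows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SCCSData
from .model import EstimationError, IrrEstimate, SCCSModel, SCCSResults
from .records import (
    CodeGroup,
    DrugClass,
    build_episodes,
)
from .segmentation import (
    EXPOSED,
    WASHOUT,
    PatientRuns,
    place_event,
    segment_patient,
)
from .windows import build_window, select_incident_event

log = logging.getLogger(__name__)

DEFAULT_OUTCOMES = ("psychosis", "hallucination", "other_psychotic")


@dataclass(frozen=True)
class ScenarioConfig:
    """One analysis configuration (the primary analysis is a scenario too)."""

    name: str
    pre_exposure_days: int = 90
    washout_days: int = 0
    extension_weeks: int = 0
    age_band_months: int = 12
    min_exposure_weeks: int = 0
    censor_psychotropics: bool = False
    exclude_substance: bool = False
    outcomes: tuple = DEFAULT_OUTCOMES
    drop_first_day_events: bool = False
    window_start_rule: str = "default"  # "default" | "late_entry"
    study_start: date = date(2001, 1, 1)
    study_end: date = date(2014, 12, 31)
    median_rx_days: int = 70

    def __post_init__(self):
        if self.pre_exposure_days not in (0, 30, 60, 90):
            raise ValueError("pre_exposure_days must be one of 0, 30, 60, 90")
        if not 0 <= self.washout_days <= 21:
            raise ValueError("washout_days must be in 0..21")
        if not 0 <= self.extension_weeks <= 10:
            raise ValueError("extension_weeks must be in 0..10")
        if self.age_band_months not in (6, 12):
            raise ValueError("age_band_months must be 6 or 12")
        if self.min_exposure_weeks not in (0, 10):
            raise ValueError("min_exposure_weeks must be 0 or 10")
        if self.window_start_rule not in ("default", "late_entry"):
            raise ValueError("window_start_rule must be 'default' or 'late_entry'")
        unknown = set(self.outcomes) - set(DEFAULT_OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome group(s): {sorted(unknown)}")


def builtin_scenarios() -> list[ScenarioConfig]:
    """The primary analyses plus the full sensitivity battery, in report order."""
    pre90 = ScenarioConfig(name="primary_pre90")
    scenarios = [
        ScenarioConfig(name="primary", pre_exposure_days=0),
        pre90,
        replace(pre90, name="age_band_6m", age_band_months=6),
        replace(pre90, name="min_exposure_10w", min_exposure_weeks=10),
        replace(pre90, name="censor_psychotropics", censor_psychotropics=True),
        replace(pre90, name="exclude_substance", exclude_substance=True),
        replace(pre90, name="psychosis_only", outcomes=("psychosis", "other_psychotic")),
        replace(pre90, name="drop_first_day", drop_first_day_events=True),
        replace(pre90, name="washout_7", washout_days=7),
        replace(pre90, name="washout_14", washout_days=14),
        replace(pre90, name="washout_21", washout_days=21),
        replace(pre90, name="late_entry", window_start_rule="late_entry"),
        replace(pre90, name="pre_60", pre_exposure_days=60),
        replace(pre90, name="pre_30", pre_exposure_days=30),
    ]
    for weeks in range(1, 11):
        scenarios.append(replace(pre90, name=f"extension_{weeks}w", extension_weeks=weeks))
    return scenarios


@dataclass
class ScenarioReport:
    """Outcome of one scenario run."""

    name: str
    scenario: ScenarioConfig
    n_cases: int
    estimates: list  # of IrrEstimate (pre-exposure first when present)
    person_time: dict
    funnel: dict
    status: str = "ok"  # "ok" | "estimation_error"
    message: str = ""
    results: SCCSResults | None = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.name,
            "n_cases": self.n_cases,
            "status": self.status,
            "message": self.message,
            "estimates": [
                {
                    "term": e.term,
                    "irr": e.irr,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                }
                for e in self.estimates
            ],
            "person_time": self.person_time,
            "funnel": self.funnel,
            "diagnostics": self.results.to_dict() if self.results is not None else None,
        }


_ADHD_PREFIX = "314"


def _first_dates(data: SCCSData, pid: str):
    """(censor date map, first MPH date, first ADHD diagnosis date)."""
    censor: dict[DrugClass, date] = {}
    first_mph: date | None = None
    for rx in data.prescriptions_for(pid):
        if rx.drug_class == DrugClass.MPH:
            if first_mph is None or rx.start_date < first_mph:
                first_mph = rx.start_date
        elif rx.drug_class in censor:
            censor[rx.drug_class] = min(censor[rx.drug_class], rx.start_date)
        else:
            censor[rx.drug_class] = rx.start_date
    first_adhd: date | None = None
    for ev in data.events_for(pid):
        if ev.code.split(".", 1)[0] == _ADHD_PREFIX:
            first_adhd = ev.event_date
            break
    return censor, first_mph, first_adhd


def collect_intervals(
    data: SCCSData, scenario: ScenarioConfig
) -> tuple[list[PatientRuns], dict]:
    """Run the pre-model pipeline for every patient under one scenario.

    Returns the retained cases' run tables plus the exclusion funnel.
    """
    funnel = {
        "patients_total": len(data.patients),
        "no_mph_prescription": 0,
        "substance_excluded": 0,
        "window_ineligible": 0,
        "prior_event_excluded": 0,
        "no_incident_event": 0,
        "event_in_washout": 0,
        "first_day_event_dropped": 0,
        "below_min_exposure": 0,
        "cases_analysed": 0,
    }
    kept: list[PatientRuns] = []
    for patient in data.patients:
        pid = patient.patient_id
        events = data.events_for(pid)
        if scenario.exclude_substance and any(
            e.code_group == CodeGroup.SUBSTANCE for e in events
        ):
            funnel["substance_excluded"] += 1
            continue
        censor, first_mph, first_adhd = _first_dates(data, pid)
        if first_mph is None:
            funnel["no_mph_prescription"] += 1
            continue
        start_override = None
        if scenario.window_start_rule == "late_entry":
            start_override = min(d for d in (first_adhd, first_mph) if d is not None)
        window = build_window(patient, censor, scenario, start_override=start_override)
        if not window.eligible:
            funnel["window_ineligible"] += 1
            continue
        event, status = select_incident_event(events, window, scenario)
        if status == "excluded_prior_event":
            funnel["prior_event_excluded"] += 1
            continue
        if event is None:
            funnel["no_incident_event"] += 1
            continue
        mph_rxs = [
            rx for rx in data.prescriptions_for(pid) if rx.drug_class == DrugClass.MPH
        ]
        episodes = build_episodes(mph_rxs, scenario.median_rx_days)
        runs = segment_patient(window, episodes, patient.date_of_birth, scenario)
        if scenario.min_exposure_weeks:
            exposed_days = int(runs.length[runs.cat == EXPOSED].sum())
            if exposed_days <= 7 * scenario.min_exposure_weeks:
                funnel["below_min_exposure"] += 1
                continue
        placement = place_event(runs, event, scenario)
        if placement == "event_in_washout":
            funnel["event_in_washout"] += 1
            continue
        if placement == "dropped_first_day":
            funnel["first_day_event_dropped"] += 1
            continue
        kept.append(runs)
    funnel["cases_analysed"] = len(kept)
    return kept, funnel


def runs_to_table(runs_list: Sequence[PatientRuns]) -> pd.DataFrame:
    """Stack per-patient run tables into the model's interval table."""
    pids, lengths, cats, bands, seasons, evs = [], [], [], [], [], []
    for runs in runs_list:
        keep = runs.cat != WASHOUT
        n = int(keep.sum())
        pids.append(np.repeat(runs.patient_id, n))
        lengths.append(runs.length[keep])
        cats.append(runs.cat[keep])
        bands.append(runs.age_band[keep])
        seasons.append(runs.season[keep])
        evs.append(runs.events[keep])
    if not pids:
        return pd.DataFrame(
            columns=["patient_id", "category", "age_band", "season", "length_days", "events"]
        )
    return pd.DataFrame(
        {
            "patient_id": np.concatenate(pids),
            "category": np.concatenate(cats).astype(np.int8),
            "age_band": np.concatenate(bands).astype(np.int64),
            "season": np.concatenate(seasons).astype(np.int64),
            "length_days": np.concatenate(lengths).astype(np.int64),
            "events": np.concatenate(evs).astype(np.int64),
        }
    )


def person_time_summary(table: pd.DataFrame) -> dict:
    """Events and patient-years in exposed versus all unexposed person-time."""
    exposed = table["category"] == EXPOSED if table["category"].dtype != object else (
        table["category"] == "exposed"
    )
    py = 365.25
    return {
        "events_exposed": int(table.loc[exposed, "events"].sum()),
        "patient_years_exposed": round(float(table.loc[exposed, "length_days"].sum()) / py, 1),
        "events_unexposed": int(table.loc[~exposed, "events"].sum()),
        "patient_years_unexposed": round(
            float(table.loc[~exposed, "length_days"].sum()) / py, 1
        ),
    }


def run_scenario(data: SCCSData, scenario: ScenarioConfig) -> ScenarioReport:
    """Execute one scenario end to end; estimation failures are reported, not raised."""
    kept, funnel = collect_intervals(data, scenario)
    table = runs_to_table(kept)
    n_cases = funnel["cases_analysed"]
    person_time = person_time_summary(table) if len(table) else {}
    try:
        if n_cases < 2:
            raise EstimationError(f"only {n_cases} case(s) available")
        model = SCCSModel(table)
        results = model.fit()
    except EstimationError as exc:
        log.warning("scenario %s: %s", scenario.name, exc)
        return ScenarioReport(
            scenario.name, scenario, n_cases, [], person_time, funnel,
            status="estimation_error", message=str(exc),
        )
    estimates = []
    for term in ("pre_exposure", "exposed"):
        if term in results.params.index:
            estimates.append(results.wald(term))
    funnel["noninformative_dropped"] = results.n_dropped_noninformative
    return ScenarioReport(
        scenario.name, scenario, n_cases, estimates, person_time, funnel, results=results
    )


def run_battery(
    data: SCCSData, scenarios: Sequence[ScenarioConfig] | None = None
) -> list[ScenarioReport]:
    return [run_scenario(data, sc) for sc in scenarios or builtin_scenarios()]


# ---------------------------------------------------------------------------
# reporting


def _row_label(term: str, scenario: ScenarioConfig) -> str:
    if term == "pre_exposure":
        return f"{scenario.pre_exposure_days} days before first MPH treatment"
    if term == "exposed":
        return "Period with MPH treatment"
    return term


def render_text(reports: Sequence[ScenarioReport]) -> str:
    lines = []
    width = 44
    for report in reports:
        lines.append(f"{report.name} (n={report.n_cases})")
        if report.status != "ok":
            lines.append(f"  {'—':<{width}} — | — | —   [{report.message}]")
        else:
            for est in report.estimates:
                label = _row_label(est.term, report.scenario)
                lines.append(
                    f"  {label:<{width}} {est.format_irr_ci()} | {est.format_p()}"
                )
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"


def render_frame(reports: Sequence[ScenarioReport]) -> pd.DataFrame:
    rows = []
    for report in reports:
        if report.status != "ok" or not report.estimates:
            rows.append(
                {
                    "scenario": report.name,
                    "n_cases": report.n_cases,
                    "term": "",
                    "irr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "status": report.status,
                }
            )
            continue
        for est in report.estimates:
            rows.append(
                {
                    "scenario": report.name,
                    "n_cases": report.n_cases,
                    "term": est.term,
                    "irr": est.irr,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_value": est.p_value,
                    "status": report.status,
                }
            )
    return pd.DataFrame(rows)


def render_json(reports: Sequence[ScenarioReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True)
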