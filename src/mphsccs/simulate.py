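"""Synthetic cohort generator for the SCCS pipeline.

Simulates patients with episodic MPH prescriptions and a piecewise-constant
daily hazard of a first psychotic event,

.. math::

    \\lambda(t) = \\lambda_0 \\cdot e^{\\gamma\\,\\mathrm{ageband}(t)}
        \\cdot s_{\\mathrm{quarter}(t)}
        \\cdot \\rho_{\\mathrm{exp}}^{[\\mathrm{exposed}(t)]}
        \\cdot \\rho_{\\mathrm{pre}}^{[\\mathrm{pre}(t)]},

with the first event drawn by exact inversion of the cumulative hazard on
the day grid.  The grid uses the same category / age-band / season
definitions as the analysis, so the simulated law is exactly the model the
fitter assumes and parameter-recovery checks are sharp.

Case cohorts condition on the first event falling inside the observation
window (the SCCS sampling rule).  Because events are rare (~6 per 10,000
patient-years at the default baseline rate), plain rejection sampling would
be slow; ``simulate_cases`` therefore uses an exact two-stage rejection
scheme: a cheap vectorised upper envelope on the total hazard decided from
the date of birth alone, followed by the exact acceptance ratio for
envelope-passed candidates.  The resulting distribution is identical to
naive rejection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np

from ._calendar import (
    CAL_START,
    DOM,
    MONTH_INDEX,
    age_months_grid,
    anniversary,
    ord_ymd,
    season_grid,
)
from .dataset import SCCSData
from .records import (
    CodeGroup,
    DrugClass,
    EventRecord,
    PatientRecord,
    PrescriptionRecord,
    SameDayOrder,
    Sex,
    write_events,
    write_patients,
    write_prescriptions,
)
from .segmentation import EXPOSED, PRE_EXPOSURE, category_grid

log = logging.getLogger(__name__)

PSYCHOSIS_CODES = ("298.0", "298.1", "298.3", "298.8", "298.9")


class SimulationAbort(RuntimeError):
    """The configured hazard is too low to ever produce a case."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults emulate the study population: observation between ages 6 and 19
    within 2001-2014 (about ten years of follow-up per patient), episodic
    MPH prescriptions with a median length of 70 days totalling about two
    years on-medication, a first-event rate near 6 per 10,000 patient-years,
    an elevated rate in the 90 days before the first prescription, mild age
    and seasonal trends, and occasional switches to atomoxetine (censoring).
    """

    n_cases_target: int = 100
    seed: int = 0
    baseline_rate_per_day: float = 1.7e-6
    true_irr_exposed: float = 1.0
    true_irr_pre: float = 4.64
    pre_exposure_days: int = 90
    age_log_trend_per_band: float = 0.10
    season_multipliers: tuple = (0.90, 1.00, 0.95, 1.15)
    episodes_per_patient_mean: float = 9.0
    episode_duration_median_days: float = 70.0
    episode_duration_log_sd: float = 0.6
    gap_mean_days: float = 60.0
    dob_year_range: tuple = (1994, 2004)
    p_atomoxetine_switch: float = 0.05
    p_event_first_day_before_flag: float = 0.5
    # cohort dressing (does not enter the hazard)
    p_adhd_diagnosis: float = 0.75
    p_male: float = 0.70
    p_missing_end_date: float = 0.01
    p_dose_quantity_given_missing: float = 0.8
    first_start_window_frac: float = 0.35
    p_hallucination: float = 0.20
    study_start: date = date(2001, 1, 1)
    study_end: date = date(2014, 12, 31)
    n_noncases: int = 0

    def __post_init__(self):
        if self.n_cases_target < 1:
            raise ValueError("n_cases_target must be >= 1")
        if self.baseline_rate_per_day < 0:
            raise ValueError("baseline_rate_per_day must be non-negative")
        for name in ("true_irr_exposed", "true_irr_pre"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.season_multipliers) != 4 or any(s <= 0 for s in self.season_multipliers):
            raise ValueError("season_multipliers must be 4 positive numbers")
        mean = sum(self.season_multipliers) / 4.0
        if abs(mean - 1.0) > 1e-9:
            object.__setattr__(
                self,
                "season_multipliers",
                tuple(s / mean for s in self.season_multipliers),
            )
        for name in (
            "episodes_per_patient_mean",
            "episode_duration_median_days",
            "episode_duration_log_sd",
            "gap_mean_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "p_atomoxetine_switch",
            "p_event_first_day_before_flag",
            "p_adhd_diagnosis",
            "p_male",
            "p_missing_end_date",
            "p_dose_quantity_given_missing",
            "p_hallucination",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, date):
                out[key] = value.isoformat()
            elif isinstance(value, tuple):
                out[key] = list(value)
            else:
                out[key] = value
        return out


@dataclass
class _Structure:
    """One simulated patient before event sampling (ordinals, inclusive)."""

    dob: date
    window_start: int
    window_end: int  # after atomoxetine censoring
    episodes: list  # [(start, end)], may extend past window_end
    atomoxetine_ord: int | None
    adhd_ord: int | None


@dataclass
class SimulatedCohort:
    """Synthetic patients/prescriptions/events plus the generating truth."""

    patients: list
    prescriptions: list
    events: list
    truth: SimulationConfig | None = None

    def to_data(self) -> SCCSData:
        return SCCSData(list(self.patients), list(self.prescriptions), list(self.events))

    def to_csv(self, directory: str | Path) -> dict:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": directory / "patients.csv",
            "prescriptions": directory / "prescriptions.csv",
            "events": directory / "events.csv",
        }
        write_patients(self.patients, paths["patients"])
        write_prescriptions(self.prescriptions, paths["prescriptions"])
        write_events(self.events, paths["events"])
        return paths


# ---------------------------------------------------------------------------
# hazard machinery


def hazard_grid(config: SimulationConfig, structure: _Structure) -> np.ndarray:
    """True per-day event hazard over the patient's observation window."""
    ws, we = structure.window_start, structure.window_end
    cat = category_grid(
        ws, we, structure.episodes, pre_exposure_days=config.pre_exposure_days
    )
    band = age_months_grid(ws, we, structure.dob) // 12
    season = season_grid(ws, we)
    smult = np.asarray(config.season_multipliers)[season - 1]
    mult = smult * np.exp(config.age_log_trend_per_band * band)
    irr = np.ones(len(cat))
    irr[cat == EXPOSED] = config.true_irr_exposed
    irr[cat == PRE_EXPOSURE] = config.true_irr_pre
    return config.baseline_rate_per_day * mult * irr


def _sample_event_day(cum: np.ndarray, rng: np.random.Generator) -> int | None:
    """First-event day by exact inversion; None if the event falls past the window."""
    total = cum[-1]
    e = rng.exponential()
    if e >= total:
        return None
    return int(np.searchsorted(cum, e, side="left"))


def _conditional_event_day(cum: np.ndarray, rng: np.random.Generator) -> int:
    """Event day given that the first event falls inside the window."""
    total = cum[-1]
    v = rng.random() * (-math.expm1(-total))
    e = -math.log1p(-v)
    return int(np.searchsorted(cum, e, side="left"))


# ---------------------------------------------------------------------------
# structure generation


def _window_for_dob(config: SimulationConfig, dob: date) -> tuple[int, int]:
    ws = max(config.study_start.toordinal(), anniversary(dob, 6))
    we = min(config.study_end.toordinal(), anniversary(dob, 20) - 1)
    return ws, we


def _draw_structure(
    config: SimulationConfig, rng: np.random.Generator, dob: date, ws: int, we: int
) -> _Structure:
    D = we - ws + 1
    n_ep = 1 + rng.poisson(max(0.0, config.episodes_per_patient_mean - 1.0))
    durations = np.maximum(
        1,
        np.rint(
            rng.lognormal(
                math.log(config.episode_duration_median_days),
                config.episode_duration_log_sd,
                n_ep,
            )
        ),
    ).astype(np.int64)
    gaps = np.maximum(1, np.rint(rng.exponential(config.gap_mean_days, n_ep))).astype(
        np.int64
    )
    first_start = ws + int(rng.integers(0, max(1, int(D * config.first_start_window_frac))))
    episodes = []
    start = first_start
    for i in range(n_ep):
        if start > we:
            break
        episodes.append((start, start + int(durations[i]) - 1))
        start = episodes[-1][1] + 1 + int(gaps[i])

    atx_ord = None
    if rng.random() < config.p_atomoxetine_switch:
        atx_ord = ws + int(rng.integers(0, D))
    adhd_ord = None
    if rng.random() < config.p_adhd_diagnosis:
        adhd_ord = max(ws, first_start - 1 - int(rng.exponential(180.0)))

    we_eff = min(we, atx_ord - 1) if atx_ord is not None else we
    return _Structure(dob, ws, we_eff, episodes, atx_ord, adhd_ord)


def _draw_dob(config: SimulationConfig, rng: np.random.Generator) -> date:
    y0, y1 = config.dob_year_range
    # day-of-month capped at 28 so every birthday exists in every year
    return date(
        int(rng.integers(y0, y1 + 1)),
        int(rng.integers(1, 13)),
        int(rng.integers(1, 29)),
    )


# ---------------------------------------------------------------------------
# record emission


def _emit_records(
    config: SimulationConfig,
    rng: np.random.Generator,
    pid: str,
    structure: _Structure,
    event_ord: int | None,
):
    sex = Sex.MALE if rng.random() < config.p_male else Sex.FEMALE
    patient = PatientRecord(pid, structure.dob, None, sex)

    prescriptions = []
    for s, e in structure.episodes:
        start = date.fromordinal(s)
        duration = e - s + 1
        if rng.random() >= config.p_missing_end_date:
            prescriptions.append(
                PrescriptionRecord(pid, DrugClass.MPH, start, date.fromordinal(e), 20.0, None)
            )
        elif rng.random() < config.p_dose_quantity_given_missing:
            prescriptions.append(
                PrescriptionRecord(pid, DrugClass.MPH, start, None, 20.0, 20.0 * duration)
            )
        else:
            prescriptions.append(PrescriptionRecord(pid, DrugClass.MPH, start, None, None, None))
    if structure.atomoxetine_ord is not None:
        s = structure.atomoxetine_ord
        prescriptions.append(
            PrescriptionRecord(
                pid,
                DrugClass.ATOMOXETINE,
                date.fromordinal(s),
                date.fromordinal(s + 27),
                None,
                None,
            )
        )

    events = []
    if structure.adhd_ord is not None:
        events.append(
            EventRecord(
                pid,
                date.fromordinal(structure.adhd_ord),
                "314.00",
                CodeGroup.NON_OUTCOME,
                SameDayOrder.UNKNOWN,
            )
        )
    if event_ord is not None:
        if rng.random() < config.p_hallucination:
            code, group = "780.1", CodeGroup.HALLUCINATION
        else:
            code = PSYCHOSIS_CODES[int(rng.integers(0, len(PSYCHOSIS_CODES)))]
            group = CodeGroup.PSYCHOSIS
        order = SameDayOrder.UNKNOWN
        if any(event_ord == s for s, _ in structure.episodes):
            order = (
                SameDayOrder.BEFORE_TREATMENT
                if rng.random() < config.p_event_first_day_before_flag
                else SameDayOrder.AFTER_TREATMENT
            )
        events.append(EventRecord(pid, date.fromordinal(event_ord), code, group, order))
    return patient, prescriptions, events


# ---------------------------------------------------------------------------
# public operations


def simulate_patient(config: SimulationConfig, rng: np.random.Generator, pid: str = "P1"):
    """Draw one patient unconditionally.

    Returns ``(patient, prescriptions, events)`` where the last element of
    ``events`` is the incident psychotic event when one occurred inside the
    observation window.
    """
    dob = _draw_dob(config, rng)
    ws, we = _window_for_dob(config, dob)
    if ws > we:
        return PatientRecord(pid, dob, None, Sex.UNKNOWN), [], []
    structure = _draw_structure(config, rng, dob, ws, we)
    event_ord = None
    if structure.window_start <= structure.window_end and config.baseline_rate_per_day > 0:
        cum = np.cumsum(hazard_grid(config, structure))
        event_ord = _sample_event_day(cum, rng)
        if event_ord is not None:
            event_ord += structure.window_start
    return _emit_records(config, rng, pid, structure, event_ord)


def _stage1_envelope(config: SimulationConfig, years, months, days):
    """Vectorised per-draw upper bound on P(first event in window)."""
    bday6 = ord_ymd(years + 6, months, days)
    bday20 = ord_ymd(years + 20, months, days)
    ws = np.maximum(config.study_start.toordinal(), bday6)
    we = np.minimum(config.study_end.toordinal(), bday20 - 1)
    D = we - ws + 1
    valid = D > 0
    Dv = np.where(valid, D, 1)

    def band_at(ord_arr):
        mi = MONTH_INDEX[ord_arr - CAL_START]
        dob_mi = (years - 1980) * 12 + (months - 1)
        return (mi - dob_mi - (DOM[ord_arr - CAL_START] < days)) // 12

    trend = config.age_log_trend_per_band
    a_lo = np.exp(trend * band_at(np.where(valid, ws, CAL_START)))
    a_hi = np.exp(trend * band_at(np.where(valid, we, CAL_START)))
    a_max = np.maximum(a_lo, a_hi)
    s_max = max(config.season_multipliers)
    lam_up = (
        config.baseline_rate_per_day
        * a_max
        * s_max
        * (
            Dv
            + config.pre_exposure_days * max(0.0, config.true_irr_pre - 1.0)
            + Dv * max(0.0, config.true_irr_exposed - 1.0)
        )
    )
    p_up = np.where(valid, np.minimum(1.0, lam_up), 0.0)
    return ws, we, p_up


def simulate_cases(config: SimulationConfig) -> SimulatedCohort:
    """Simulate until ``n_cases_target`` case patients are collected.

    Case = the patient's first psychotic event falls inside their observation
    window.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    patients, prescriptions, events = [], [], []
    n_cases = 0
    batch = 8192
    first_batch = True
    while n_cases < config.n_cases_target:
        years = rng.integers(
            config.dob_year_range[0], config.dob_year_range[1] + 1, batch
        )
        months = rng.integers(1, 13, batch)
        days = rng.integers(1, 29, batch)
        u1 = rng.random(batch)
        ws, we, p_up = _stage1_envelope(config, years, months, days)
        if first_batch:
            if float(np.mean(p_up)) < 1e-6:
                raise SimulationAbort(
                    "expected case yield below 1e-6 per draw; "
                    "baseline_rate_per_day or the IRRs are too small"
                )
            first_batch = False
        for idx in np.flatnonzero(u1 < p_up):
            dob = date(int(years[idx]), int(months[idx]), int(days[idx]))
            structure = _draw_structure(config, rng, dob, int(ws[idx]), int(we[idx]))
            if structure.window_start > structure.window_end:
                continue
            cum = np.cumsum(hazard_grid(config, structure))
            total = float(cum[-1])
            accept_p = -math.expm1(-total) / float(p_up[idx])
            if rng.random() >= accept_p:
                continue
            event_ord = structure.window_start + _conditional_event_day(cum, rng)
            n_cases += 1
            pid = f"P{n_cases:06d}"
            pat, rxs, evs = _emit_records(config, rng, pid, structure, event_ord)
            patients.append(pat)
            prescriptions.extend(rxs)
            events.extend(evs)
            if n_cases >= config.n_cases_target:
                break

    for i in range(config.n_noncases):
        pid = f"N{i + 1:06d}"
        while True:
            pat, rxs, evs = simulate_patient(config, rng, pid)
            if not any(e.code_group != CodeGroup.NON_OUTCOME for e in evs):
                break
        patients.append(pat)
        prescriptions.extend(rxs)
        events.extend(evs)

    return SimulatedCohort(patients, prescriptions, events, truth=config)


# ---------------------------------------------------------------------------
# deterministic toy fixtures


FIXTURE_NAMES = ("irr3_pair", "no_information", "day1_tie")


def toy_fixture(name: str) -> SimulatedCohort:
    """Small hand-constructed cohorts with known closed-form behaviour.

    ``irr3_pair``
        Two patients, each with a 400-day window (censored by atomoxetine)
        split into 100 exposed and 300 baseline days; one event in each
        category.  With no pre-exposure window and no age/season adjustment
        the exposed IRR is exactly 3.
    ``no_information``
        Two patients whose windows are entirely exposed: no within-person
        contrast, so fitting raises an estimation error.
    ``day1_tie``
        One patient whose event falls on the first day of an episode with the
        before-treatment flag set: the event is classified as pre-exposure.
    """
    if name == "irr3_pair":
        dob = date(2000, 1, 1)
        patients, rxs, evs = [], [], []
        for pid, event_day, code in (
            ("A", date(2006, 12, 1), "298.9"),
            ("B", date(2006, 3, 1), "298.9"),
        ):
            patients.append(PatientRecord(pid, dob, None, Sex.MALE))
            rxs.append(
                PrescriptionRecord(pid, DrugClass.MPH, date(2006, 10, 28), date(2007, 2, 4))
            )
            rxs.append(
                PrescriptionRecord(
                    pid, DrugClass.ATOMOXETINE, date(2007, 2, 5), date(2007, 3, 4)
                )
            )
            evs.append(EventRecord(pid, event_day, code, CodeGroup.PSYCHOSIS))
        return SimulatedCohort(patients, rxs, evs)
    if name == "no_information":
        patients, rxs, evs = [], [], []
        for pid, event_day in (("C", date(2006, 6, 15)), ("D", date(2006, 9, 1))):
            patients.append(PatientRecord(pid, date(2000, 1, 1), None, Sex.FEMALE))
            rxs.append(
                PrescriptionRecord(pid, DrugClass.MPH, date(2006, 1, 1), date(2007, 2, 4))
            )
            rxs.append(
                PrescriptionRecord(
                    pid, DrugClass.ATOMOXETINE, date(2007, 2, 5), date(2007, 3, 4)
                )
            )
            evs.append(EventRecord(pid, event_day, "298.0", CodeGroup.PSYCHOSIS))
        return SimulatedCohort(patients, rxs, evs)
    if name == "day1_tie":
        pid = "E"
        return SimulatedCohort(
            [PatientRecord(pid, date(2000, 1, 1), None, Sex.MALE)],
            [PrescriptionRecord(pid, DrugClass.MPH, date(2010, 5, 1), date(2010, 7, 9))],
            [
                EventRecord(
                    pid,
                    date(2010, 5, 1),
                    "298.9",
                    CodeGroup.PSYCHOSIS,
                    SameDayOrder.BEFORE_TREATMENT,
                )
            ],
        )
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
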