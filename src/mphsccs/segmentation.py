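"""Partition observation windows into analysis intervals.

Each patient's window is tiled with intervals that are homogeneous in
exposure category, age band and season:

* ``exposed``      — days covered by an MPH episode (optionally extended by a
  configurable number of weeks after each episode end);
* ``pre_exposure`` — a fixed window (90 days by default) immediately before
  the *first-ever* MPH episode, absorbing event-driven treatment initiation;
* ``excluded_washout`` — days immediately before the first episode removed
  from analysed person-time entirely (sensitivity variants);
* ``baseline``     — everything else.

Precedence on any day is exposed > washout > pre-exposure > baseline.  Age
bands are anchored at the birthday (12- or 6-month width) and season is the
calendar quarter.  The implementation classifies every day of the window on
a vectorised day grid and then collapses runs, which makes the precedence
rules and the tiling invariant trivially correct.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from datetime import date
from typing import Sequence

import numpy as np

from ._calendar import age_months_grid, season_grid
from .records import EventRecord, ExposureEpisode, SameDayOrder
from .windows import ObservationWindow

# integer category codes used on the day grid
BASELINE, PRE_EXPOSURE, EXPOSED, WASHOUT = 0, 1, 2, 3

_CATEGORY_NAMES = {
    BASELINE: "baseline",
    PRE_EXPOSURE: "pre_exposure",
    EXPOSED: "exposed",
    WASHOUT: "excluded_washout",
}


class Category(str, enum.Enum):
    BASELINE = "baseline"
    PRE_EXPOSURE = "pre_exposure"
    EXPOSED = "exposed"
    EXCLUDED_WASHOUT = "excluded_washout"


@dataclass(frozen=True)
class ExposureSegment:
    patient_id: str
    start_date: date
    end_date: date
    category: Category

    @property
    def length_days(self) -> int:
        return self.end_date.toordinal() - self.start_date.toordinal() + 1


@dataclass(frozen=True)
class AnalysisInterval:
    """An atomic slice of person-time, homogeneous in all model covariates."""

    patient_id: str
    category: Category
    age_band: int
    season: int
    start_date: date
    end_date: date
    events: int = 0

    @property
    def length_days(self) -> int:
        return self.end_date.toordinal() - self.start_date.toordinal() + 1


@dataclass
class PatientRuns:
    """Run-level interval table for one patient (array fast path).

    ``start``/``length``/``cat``/``age_band``/``season`` cover the whole
    window *including* washout runs; analysis rows are ``cat != WASHOUT``.
    """

    patient_id: str
    window_start: int
    window_end: int
    start: np.ndarray
    length: np.ndarray
    cat: np.ndarray
    age_band: np.ndarray
    season: np.ndarray
    events: np.ndarray
    episode_first_days: np.ndarray  # in-window first treatment days

    @property
    def washout_days(self) -> int:
        return int(self.length[self.cat == WASHOUT].sum())


# ---------------------------------------------------------------------------
# day-grid construction


def _extend_and_merge(episodes: list[tuple[int, int]], extension_days: int, we: int):
    if not episodes:
        return []
    extended = sorted((s, min(e + extension_days, we)) for s, e in episodes)
    merged = [list(extended[0])]
    for s, e in extended[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def category_grid(
    ws: int,
    we: int,
    episodes_ord: Sequence[tuple[int, int]],
    pre_exposure_days: int = 90,
    washout_days: int = 0,
    extension_days: int = 0,
) -> np.ndarray:
    """Per-day exposure category over the inclusive window [ws, we].

    ``episodes_ord`` are merged exposure episodes as inclusive ordinal pairs,
    *unclipped*: the pre-exposure and washout windows anchor at the first-ever
    episode start even when that start precedes the window.
    """
    n = we - ws + 1
    cat = np.zeros(n, dtype=np.int8)
    if not episodes_ord:
        return cat
    first_start = min(s for s, _ in episodes_ord)

    def paint(lo: int, hi: int, value: int):
        lo, hi = max(lo, ws), min(hi, we)
        if lo <= hi:
            cat[lo - ws : hi - ws + 1] = value

    if pre_exposure_days > 0:
        paint(first_start - pre_exposure_days, first_start - 1, PRE_EXPOSURE)
    if washout_days > 0:
        paint(first_start - washout_days, first_start - 1, WASHOUT)
    # extension is applied before window clipping so that an episode ending
    # just outside the window still contributes its extended tail
    for s, e in _extend_and_merge(list(episodes_ord), extension_days, we):
        paint(s, e, EXPOSED)
    return cat


def _runs(
    patient_id: str,
    ws: int,
    we: int,
    cat: np.ndarray,
    band: np.ndarray,
    season: np.ndarray,
    episode_first_days: np.ndarray,
) -> PatientRuns:
    code = (cat.astype(np.int32) * 512 + band.astype(np.int32)) * 8 + season
    cuts = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [len(code)]))
    return PatientRuns(
        patient_id=patient_id,
        window_start=ws,
        window_end=we,
        start=starts + ws,
        length=(ends - starts).astype(np.int64),
        cat=cat[starts],
        age_band=band[starts].astype(np.int16),
        season=season[starts].astype(np.int8),
        events=np.zeros(len(starts), dtype=np.int8),
        episode_first_days=episode_first_days,
    )


def segment_patient(
    window: ObservationWindow,
    episodes: Sequence[ExposureEpisode],
    dob: date,
    scenario,
) -> PatientRuns:
    """Full segmentation fast path: window -> run-level interval table."""
    ws, we = window.start_date.toordinal(), window.end_date.toordinal()
    eps = [(ep.start_date.toordinal(), ep.end_date.toordinal()) for ep in episodes]
    cat = category_grid(
        ws,
        we,
        eps,
        pre_exposure_days=getattr(scenario, "pre_exposure_days", 90),
        washout_days=getattr(scenario, "washout_days", 0),
        extension_days=7 * getattr(scenario, "extension_weeks", 0),
    )
    band_months = getattr(scenario, "age_band_months", 12)
    band = age_months_grid(ws, we, dob) // band_months
    season = season_grid(ws, we)
    first_days = np.array(sorted(s for s, e in eps if ws <= s <= we), dtype=np.int64)
    return _runs(window.patient_id, ws, we, cat, band, season, first_days)


# ---------------------------------------------------------------------------
# record-level API


def classify_exposure(
    window: ObservationWindow,
    episodes: Sequence[ExposureEpisode],
    scenario,
) -> list[ExposureSegment]:
    """Tile the window with exposure-category segments (before age/season cuts)."""
    ws, we = window.start_date.toordinal(), window.end_date.toordinal()
    eps = [(ep.start_date.toordinal(), ep.end_date.toordinal()) for ep in episodes]
    cat = category_grid(
        ws,
        we,
        eps,
        pre_exposure_days=getattr(scenario, "pre_exposure_days", 90),
        washout_days=getattr(scenario, "washout_days", 0),
        extension_days=7 * getattr(scenario, "extension_weeks", 0),
    )
    cuts = np.flatnonzero(np.diff(cat)) + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [len(cat)]))
    return [
        ExposureSegment(
            window.patient_id,
            date.fromordinal(ws + int(s)),
            date.fromordinal(ws + int(e) - 1),
            Category(_CATEGORY_NAMES[int(cat[s])]),
        )
        for s, e in zip(starts, ends)
    ]


def cut_by_age_and_season(
    segments: Sequence[ExposureSegment],
    dob: date,
    scenario,
) -> list[AnalysisInterval]:
    """Split segments at every (half-)birthday and season boundary.

    Washout segments are removed from analysis time here.
    """
    band_months = getattr(scenario, "age_band_months", 12)
    intervals: list[AnalysisInterval] = []
    for seg in segments:
        if seg.category == Category.EXCLUDED_WASHOUT:
            continue
        s, e = seg.start_date.toordinal(), seg.end_date.toordinal()
        band = age_months_grid(s, e, dob) // band_months
        season = season_grid(s, e)
        code = band.astype(np.int32) * 8 + season
        cuts = np.flatnonzero(np.diff(code)) + 1
        starts = np.concatenate(([0], cuts))
        ends = np.concatenate((cuts, [len(code)]))
        for lo, hi in zip(starts, ends):
            intervals.append(
                AnalysisInterval(
                    seg.patient_id,
                    seg.category,
                    int(band[lo]),
                    int(season[lo]),
                    date.fromordinal(s + int(lo)),
                    date.fromordinal(s + int(hi) - 1),
                )
            )
    return intervals


class IntervalPlacementError(RuntimeError):
    """The event day is not covered by any interval (upstream inconsistency)."""


def place_event(runs: PatientRuns, event: EventRecord, scenario=None) -> str:
    """Place the incident event on the run table in place; returns a status.

    Status is ``"placed"``, ``"event_in_washout"`` (patient must be dropped)
    or ``"dropped_first_day"`` (first-day removal sensitivity rule).
    """
    d = event.event_date.toordinal()
    if not runs.window_start <= d <= runs.window_end:
        raise IntervalPlacementError(
            f"patient {runs.patient_id}: event {event.event_date} outside window"
        )
    is_first_day = bool(runs.episode_first_days.size) and d in runs.episode_first_days
    if is_first_day and getattr(scenario, "drop_first_day_events", False):
        return "dropped_first_day"
    if is_first_day and event.same_day_order == SameDayOrder.BEFORE_TREATMENT:
        # event preceded that day's first dose: attribute it to the period
        # ending the previous day (pre-exposure or baseline) when one exists
        if d - 1 >= runs.window_start:
            d = d - 1
    idx = int(np.searchsorted(runs.start, d, side="right")) - 1
    if idx < 0 or d >= runs.start[idx] + runs.length[idx]:
        raise IntervalPlacementError(
            f"patient {runs.patient_id}: day {d} not covered by any interval"
        )
    if runs.cat[idx] == WASHOUT:
        return "event_in_washout"
    runs.events[idx] += 1
    return "placed"


def attach_event(
    intervals: Sequence[AnalysisInterval],
    event: EventRecord,
    episodes: Sequence[ExposureEpisode],
    scenario=None,
) -> tuple[list[AnalysisInterval], str]:
    """Record-level counterpart of :func:`place_event`.

    Returns the interval list with the event placed plus a status.  Note that
    washout days are already absent from ``intervals``; an event falling on a
    washout day therefore reports ``"event_in_washout"``.
    """
    d = event.event_date.toordinal()
    first_days = {ep.start_date.toordinal() for ep in episodes}
    if d in first_days and getattr(scenario, "drop_first_day_events", False):
        return list(intervals), "dropped_first_day"
    if d in first_days and event.same_day_order == SameDayOrder.BEFORE_TREATMENT:
        d = d - 1
    out = list(intervals)
    for i, itv in enumerate(out):
        if itv.start_date.toordinal() <= d <= itv.end_date.toordinal():
            out[i] = replace(itv, events=itv.events + 1)
            return out, "placed"
    lo = min(itv.start_date.toordinal() for itv in out)
    hi = max(itv.end_date.toordinal() for itv in out)
    if lo <= d <= hi:
        return list(intervals), "event_in_washout"
    raise IntervalPlacementError(
        f"patient {event.patient_id}: event day {event.event_date} not covered"
    )


def runs_to_intervals(runs: PatientRuns) -> list[AnalysisInterval]:
    """Convert the array fast path to record-level intervals (washout dropped)."""
    out = []
    for i in range(len(runs.start)):
        if runs.cat[i] == WASHOUT:
            continue
        s = int(runs.start[i])
        out.append(
            AnalysisInterval(
                runs.patient_id,
                Category(_CATEGORY_NAMES[int(runs.cat[i])]),
                int(runs.age_band[i]),
                int(runs.season[i]),
                date.fromordinal(s),
                date.fromordinal(s + int(runs.length[i]) - 1),
                int(runs.events[i]),
            )
        )
    return out
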