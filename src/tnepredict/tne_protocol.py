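"""Treat-and-extend (T&E) regimen state machine and outcome labels.

The regimen encoded here injects at every visit.  Eyes are treated at
monthly (4-week) intervals until disease activity — the presence of IRF or
SRF — first resolves.  From then on the interval is extended by 2 weeks
after an inactive assessment (to a maximum of 12 weeks) and shortened by
2 weeks after an active one (to a minimum of 4 weeks).  The opportunity to
extend is limited to two attempts: an attempt is consumed when an extension
is later revoked by recurrence-driven shortening, and after the second
revocation the interval may shorten but never re-extend.

Outcome labels derived from a simulated 52-week course:

* ``extendable`` — the eye reached an interval of at least 8 weeks and
  maintained it, i.e. received >= 2 injections at >= 8-week intervals with
  no subsequent fall-back below 8 weeks through end of follow-up;
* treatment ``pattern`` — monthly-intensive (never extended), continually
  extended (monotone extension starting by the 4th injection), or
  individualized.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .synthetic_data import EyeState, FluidKinetics, simulate_bcva

INTERVALS = (4, 6, 8, 10, 12)
MIN_INTERVAL, MAX_INTERVAL = 4, 12
MAX_EXTENSION_ATTEMPTS = 2
#: "presence" of a fluid operationalised as exceeding 1 nl total volume
DEFAULT_ACTIVITY_THRESHOLDS = {"IRF": 1.0, "SRF": 1.0}


@dataclass
class VisitRecord:
    week: int
    interval_weeks: int  # interval scheduled from this visit to the next
    injected: bool
    disease_active: bool
    bcva: float
    volumes: Dict[str, float]


@dataclass
class TreatmentCourse:
    eye_id: str
    visits: List[VisitRecord]
    extension_attempts_used: int = 0

    def intervals(self) -> List[int]:
        return [v.interval_weeks for v in self.visits]


@dataclass
class OutcomeLabels:
    eye_id: str
    extendable: bool
    pattern: str
    responder: Optional[bool] = None


def assess_activity(
    volumes: Dict[str, float], thresholds: Optional[Dict[str, float]] = None
) -> bool:
    """Disease activity: IRF or SRF above threshold.  PED/HRF never trigger."""
    thresholds = thresholds if thresholds is not None else DEFAULT_ACTIVITY_THRESHOLDS
    if any(t < 0 for t in thresholds.values()):
        raise ConfigurationError("activity thresholds must be non-negative")
    for b in ("IRF", "SRF"):
        if b not in volumes:
            raise ContractError(f"volumes must contain {b}")
    return bool(
        volumes["IRF"] > thresholds.get("IRF", 1.0)
        or volumes["SRF"] > thresholds.get("SRF", 1.0)
    )


def next_interval(
    current: int,
    active: bool,
    attempts_used: int,
    *,
    shortening_streak: bool = False,
) -> Tuple[int, int]:
    """One step of the interval rule; returns (next interval, attempts used).

    Inactive: extend by 2 weeks up to 12, unless both extension attempts are
    spent, in which case the interval is held.  Active: shorten by 2 weeks
    down to 4; the first shortening of a recurrence episode (an active
    assessment at an interval above 4 weeks that is not a continuation of an
    ongoing shortening run, flagged by ``shortening_streak``) consumes one
    extension attempt.
    """
    if current not in INTERVALS:
        raise ContractError(f"interval {current} not in {INTERVALS}")
    if active:
        used = attempts_used
        if current > MIN_INTERVAL and not shortening_streak and used < MAX_EXTENSION_ATTEMPTS:
            used += 1
        return max(current - 2, MIN_INTERVAL), used
    if attempts_used >= MAX_EXTENSION_ATTEMPTS:
        return current, attempts_used
    return min(current + 2, MAX_INTERVAL), attempts_used


def simulate_course(
    eye: EyeState,
    horizon_weeks: int = 52,
    thresholds: Optional[Dict[str, float]] = None,
    seed: Optional[int] = None,
) -> TreatmentCourse:
    """Simulate one eye's 52-week T&E course (deterministic given seed).

    Every visit injects.  The second injection always follows at week 4
    (loading dose); monthly dosing continues until the first inactive
    assessment, after which the interval rule of :func:`next_interval`
    applies.
    """
    fk = FluidKinetics(eye, seed=seed)
    week = 0
    interval = MIN_INTERVAL
    attempts = 0
    monthly_phase = True
    streak = False
    weeks: List[int] = []
    intervals: List[int] = []
    actives: List[bool] = []
    vols: List[Dict[str, float]] = []
    while week <= horizon_weeks:
        v = fk.observe()
        active = assess_activity(v, thresholds)
        if not weeks:
            nxt = MIN_INTERVAL  # loading: second injection 4 weeks after baseline
            monthly_phase = active
        elif monthly_phase and active:
            nxt = MIN_INTERVAL
        else:
            monthly_phase = False
            nxt, attempts = next_interval(
                interval, active, attempts, shortening_streak=streak
            )
            streak = active
        weeks.append(week)
        intervals.append(nxt)
        actives.append(active)
        vols.append(v)
        fk.inject()
        fk.advance(nxt)
        interval = nxt
        week += nxt
    bcva = simulate_bcva(eye, weeks)
    visits = [
        VisitRecord(
            week=w, interval_weeks=i, injected=True, disease_active=a, bcva=float(b), volumes=vv
        )
        for w, i, a, b, vv in zip(weeks, intervals, actives, bcva, vols)
    ]
    return TreatmentCourse(eye_id=eye.eye_id, visits=visits, extension_attempts_used=attempts)


def label_extendable(course: TreatmentCourse, require_maintained: bool = True) -> bool:
    """Reached and maintained an interval of >= 8 weeks with >= 2 such treatments.

    With ``require_maintained`` (default) the qualifying injections must not
    be followed by any fall-back below 8 weeks: the trailing run of
    >= 8-week intervals must contain at least two.  The permissive variant
    counts any two >= 8-week intervals regardless of later fall-back.
    """
    ints = course.intervals()
    if not ints:
        raise ContractError("course is empty")
    if not require_maintained:
        return sum(i >= 8 for i in ints) >= 2
    k = len(ints)
    while k > 0 and ints[k - 1] >= 8:
        k -= 1
    return len(ints) - k >= 2


def classify_pattern(course: TreatmentCourse) -> str:
    """Treatment-frequency pattern of one course.

    monthly_intensive: every interval 4 weeks; continually_extended:
    non-decreasing intervals with extension starting by the 4th injection;
    otherwise individualized.
    """
    ints = course.intervals()
    if not ints:
        raise ContractError("course is empty")
    if all(i == MIN_INTERVAL for i in ints):
        return "monthly_intensive"
    nondecreasing = all(a <= b for a, b in zip(ints, ints[1:]))
    if nondecreasing and any(i > MIN_INTERVAL for i in ints[:4]):
        return "continually_extended"
    return "individualized"


def label_courses(
    courses: Sequence[TreatmentCourse], require_maintained: bool = True
) -> pd.DataFrame:
    """Outcome labels for a set of courses, keyed by eye_id."""
    rows = [
        {
            "eye_id": c.eye_id,
            "extendable": label_extendable(c, require_maintained),
            "pattern": classify_pattern(c),
        }
        for c in courses
    ]
    return pd.DataFrame(rows).set_index("eye_id")


def cohort_summary(courses: Sequence[TreatmentCourse]) -> pd.DataFrame:
    """Per-visit-index mean volumes and mean BCVA change from baseline."""
    if not courses:
        raise ContractError("need at least one course")
    n_visits = max(len(c.visits) for c in courses)
    rows = []
    for j in range(n_visits):
        present = [c.visits[j] for c in courses if len(c.visits) > j]
        base = [c.visits[0].bcva for c in courses if len(c.visits) > j]
        row = {
            "visit_index": j,
            "n_eyes": len(present),
            "mean_week": float(np.mean([v.week for v in present])),
            "mean_bcva_change": float(
                np.mean([v.bcva - b0 for v, b0 in zip(present, base)])
            ),
            "mean_interval_weeks": float(np.mean([v.interval_weeks for v in present])),
        }
        for b in ("IRF", "SRF", "PED", "HRF"):
            row[f"mean_{b}_nl"] = float(np.mean([v.volumes.get(b, 0.0) for v in present]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("visit_index")


def courses_to_frame(courses: Sequence[TreatmentCourse]) -> pd.DataFrame:
    """Serialize courses to a flat table, one row per visit."""
    rows = []
    for c in courses:
        for v in c.visits:
            rows.append(
                {
                    "eye_id": c.eye_id,
                    "week": v.week,
                    "interval_weeks": v.interval_weeks,
                    "injected": v.injected,
                    "disease_active": v.disease_active,
                    "bcva": v.bcva,
                    **{f"{b}_nl": v.volumes.get(b, 0.0) for b in ("IRF", "SRF", "PED", "HRF")},
                }
            )
    return pd.DataFrame(rows)


def courses_from_frame(df: pd.DataFrame) -> List[TreatmentCourse]:
    """Inverse of :func:`courses_to_frame` (attempt counters are not stored)."""
    courses = []
    for eye_id, grp in df.groupby("eye_id", sort=False):
        grp = grp.sort_values("week")
        visits = [
            VisitRecord(
                week=int(r.week),
                interval_weeks=int(r.interval_weeks),
                injected=bool(r.injected),
                disease_active=bool(r.disease_active),
                bcva=float(r.bcva),
                volumes={b: float(getattr(r, f"{b}_nl")) for b in ("IRF", "SRF", "PED", "HRF")},
            )
            for r in grp.itertuples()
        ]
        courses.append(TreatmentCourse(eye_id=str(eye_id), visits=visits))
    return courses
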