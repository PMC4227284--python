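"""Nested case-control construction for a ward infection cohort.

Eligibility keeps infection admissions and drops direct ICU admissions and
patients with limits on life-sustaining interventions.  A case is any
admission with a qualifying deterioration event (ICU transfer, critical
care consult, rapid response, or in-hospital death); its index time is the
earliest such event.  One control per case is drawn at random from patients
who never became cases, were admitted on the same calendar day, and stayed
longer than the case's admission-to-index interval; the control's index
time is set to the same offset from admission.  Controls are used without
replacement.

This is risk-set sampling with an additional never-case restriction: a
patient who deteriorates later in the study can never serve as a control,
which the source design states explicitly even though textbook risk-set
sampling would allow it.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .records import PatientRecord, QUALIFYING_EVENTS

__all__ = ["CaseControlPair", "build_cohort", "identify_cases", "sample_controls"]


@dataclass(frozen=True)
class CaseControlPair:
    """A matched case and control sharing the admission-to-index offset."""

    case_id: str
    control_id: str
    case_index_time: datetime
    control_index_time: datetime
    admission_to_index_hours: float


def build_cohort(admissions: list, infection_codes=None):
    """Apply inclusion/exclusion rules; returns (eligible, exclusion_counts).

    Keeps admissions with an infection diagnosis (``has_infection``, or an
    ICD-9 code in ``infection_codes`` when the record carries codes), and
    drops direct ICU admissions and care-limited patients.
    """
    eligible = []
    exclusions: Counter = Counter()
    for record in admissions:
        infected = record.has_infection
        if infection_codes is not None and record.meta.get("icd9_codes"):
            infected = any(c in infection_codes for c in record.meta["icd9_codes"])
        if not infected:
            exclusions["no_infection_diagnosis"] += 1
        elif record.direct_icu_admit:
            exclusions["direct_icu_admission"] += 1
        elif record.care_limits:
            exclusions["limits_on_life_sustaining_care"] += 1
        else:
            eligible.append(record)
    return eligible, dict(exclusions)


def identify_cases(cohort: list) -> pd.DataFrame:
    """One row per case: ``patient_id`` and the earliest qualifying event as
    ``index_time``; raises on an event recorded before admission."""
    rows = []
    for record in cohort:
        events = {e: t for e, t in record.event_times.items() if e in QUALIFYING_EVENTS}
        if not events:
            continue
        for name, t in events.items():
            if t < record.admission_time:
                raise ValueError(
                    f"{record.patient_id}: event {name} precedes admission (data error)")
        index_time = min(events.values())
        rows.append({"patient_id": record.patient_id, "index_time": index_time,
                     "index_event": min(events, key=events.get),
                     "admission_to_index_hours":
                         (index_time - record.admission_time).total_seconds() / 3600.0})
    return pd.DataFrame(rows, columns=["patient_id", "index_time", "index_event",
                                       "admission_to_index_hours"])


def sample_controls(cases: pd.DataFrame, cohort: list, seed: int = 0, *,
                    match_tolerance_days: int = 0, max_widen_days: int = 3):
    """Draw one matched control per case.

    Matching is by exact admission calendar date (a ``± k``-day relaxation,
    up to ``max_widen_days``, is tried only when the exact date yields no
    candidate).  Eligible controls never had a qualifying event, have a
    length of stay strictly greater than the case's admission-to-index
    interval, and are used at most once.  Candidates are drawn uniformly at
    random under the given seed; cases with no eligible control are dropped
    and counted.

    Returns ``(pairs, n_dropped)`` where ``pairs`` is a list of
    :class:`CaseControlPair`.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.patient_id: r for r in cohort}
    controls = [r for r in cohort if not r.is_case]
    by_date: dict = {}
    for r in controls:
        by_date.setdefault(r.admission_time.date(), []).append(r.patient_id)

    pairs = []
    used: set = set()
    n_dropped = 0
    # Deterministic case order regardless of the input frame's ordering.
    for _, case_row in cases.sort_values("patient_id").iterrows():
        case = by_id[case_row["patient_id"]]
        offset_h = float(case_row["admission_to_index_hours"])
        case_date = case.admission_time.date()

        chosen = None
        for widen in range(match_tolerance_days, max_widen_days + 1):
            candidate_ids: list = []
            for d in range(-widen, widen + 1):
                candidate_ids.extend(by_date.get(case_date + timedelta(days=d), []))
            candidate_ids = sorted(
                cid for cid in set(candidate_ids)
                if cid not in used and by_id[cid].los_hours > offset_h)
            if candidate_ids:
                chosen = candidate_ids[int(rng.integers(len(candidate_ids)))]
                break
        if chosen is None:
            n_dropped += 1
            continue
        used.add(chosen)
        control = by_id[chosen]
        pairs.append(CaseControlPair(
            case_id=case.patient_id, control_id=chosen,
            case_index_time=case_row["index_time"],
            control_index_time=control.admission_time + timedelta(hours=offset_h),
            admission_to_index_hours=offset_h,
        ))
    return pairs, n_dropped


def pairs_frame(pairs: list) -> pd.DataFrame:
    """Serialize pairs to a DataFrame mirroring :class:`CaseControlPair`."""
    return pd.DataFrame([{
        "case_id": p.case_id, "control_id": p.control_id,
        "case_index_time": p.case_index_time,
        "control_index_time": p.control_index_time,
        "admission_to_index_hours": p.admission_to_index_hours,
    } for p in pairs])
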