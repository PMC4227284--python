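"""Synthetic ward-EHR cohort generator with known ground truth.

Emulates an ER-admitted infection cohort on general hospital wards: a small
fraction of admissions deteriorate (ICU transfer, consult for ICU transfer,
rapid response, or in-hospital death) at a log-normal time from admission
(median 32 h), vitals are charted every ~6 h and metabolic panels roughly
twice daily with realistic per-window availability, arterial blood gases
exist for a minority of patients, and the physiology of deteriorating
patients drifts linearly toward derangement over the final hours before the
event.  Baseline physiology is drawn from truncated normals around the same
documented normal midpoints used by the assume-normal imputation rule
(single source of truth), and the drift direction per component comes from
the same fixture's "worse" metadata.

Illness severity is modeled as a latent scalar: every admission (cases and
controls alike) carries a static baseline severity drawn from an
exponential distribution - infected ward patients are not healthy - and
cases add a linear ramp beginning ``drift_onset`` hours before the event.
Heterogeneity enters twice: a per-case log-normal multiplier on the ramp
(not every deterioration is equally fulminant) and a per-patient,
per-component gamma weight (different patients fail different organs).
Component values are shifted toward their deranged side by
``weight x severity`` baseline standard deviations.  Consciousness (AVPU)
and supplemental oxygen are deterministic functions of the latent severity.

Every draw flows from one ``numpy`` Generator seeded from the params, so an
identical ``(params, seed)`` gives a byte-identical cohort.
"""
from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np

import pandas as pd

from .records import (COMORBIDITY_FLAGS, CohortParams, LabObservation,
                      PatientRecord, VitalObservation)
from .scores import load_normal_values

__all__ = ["generate_cohort", "ground_truth"]

_VITAL_COMPONENTS = ("heart_rate", "respiratory_rate", "systolic_bp",
                     "diastolic_bp", "temperature", "spo2")
_PANEL_ANALYTES = ("wbc", "platelets", "bilirubin", "creatinine", "bun",
                   "sodium", "potassium", "bicarbonate", "hematocrit",
                   "glucose", "albumin", "lactate", "band_fraction")
_ABG_ANALYTES = ("pao2", "paco2", "ph")

_RACES = ("white", "black", "hispanic", "other")
_RACE_P = (0.23, 0.31, 0.37, 0.09)
_NON_PNEUMONIA_SOURCES = ("urinary", "skin_soft_tissue", "peritonitis", "other")
_NON_PNEUMONIA_P = (0.36, 0.07, 0.03, 0.54)

#: Latent-severity cutoffs (in baseline-SD units) mapping to the AVPU
#: consciousness level; deterministic given the latent severity.
_AVPU_CUTS = ((1.25, "A"), (2.25, "V"), (3.25, "P"), (np.inf, "U"))

#: Latent severity above which the patient is on supplemental oxygen.
_O2_CUT = 1.0


def _avpu_from_severity(severity: float) -> str:
    for cut, level in _AVPU_CUTS:
        if severity < cut:
            return level
    return "U"  # pragma: no cover


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _lognormal_from_median(rng, median, sigma):
    return float(np.exp(rng.normal(np.log(median), sigma)))


def generate_cohort(params: CohortParams | None = None) -> list:
    """Generate a synthetic ward cohort of :class:`PatientRecord`.

    Cases carry a monotone linear drift toward deranged values on every
    component from ``drift_onset`` hours before the event, scaled as
    ``drift_effect`` baseline SDs per 12 h; controls are drift-free.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    normals = load_normal_values()
    for comp, override in params.baseline_overrides.items():
        normals = {**normals, comp: {**normals[comp], **override}}

    start = datetime.fromisoformat(params.start_date)
    records = []
    for i in range(params.n_admissions):
        pid = f"P{i:05d}"
        is_case = bool(rng.random() < params.case_fraction)
        admission = (start + timedelta(days=int(rng.integers(0, params.n_days)),
                                       hours=float(rng.uniform(0, 24))))

        # --- outcome timing -------------------------------------------------
        event_times: dict = {}
        if is_case:
            tte = _lognormal_from_median(rng, params.median_time_to_event, params.tte_sigma)
            tte = float(np.clip(tte, 4.0, 24.0 * 21))
            present = {
                "icu_transfer": rng.random() < params.p_icu_transfer,
                "rapid_response": rng.random() < params.p_rapid_response,
                "death": rng.random() < params.p_death,
            }
            if not any(present.values()):
                present["rapid_response"] = True
            acute = [e for e in ("icu_transfer", "rapid_response") if present[e]]
            index_event = acute[0] if acute else "death"
            offsets = {index_event: 0.0}
            for e, p in present.items():
                if p and e not in offsets:
                    lo = 12.0 if e == "death" else 1.0
                    offsets[e] = float(rng.uniform(lo, 96.0))
            event_times = {e: admission + timedelta(hours=tte + off)
                           for e, off in offsets.items()}
            los = tte + max(offsets.values()) + _lognormal_from_median(rng, 48.0, 0.8)
        else:
            tte = np.nan
            los = _lognormal_from_median(rng, params.los_median, params.los_sigma)
            los = float(np.clip(los, 12.0, 24.0 * 30))
        discharge = admission + timedelta(hours=los)

        # --- demographics and comorbidities ---------------------------------
        col = 0 if is_case else 1
        age = int(np.clip(round(rng.normal(params.age_mean[col], params.age_sd)), 18, 100))
        sex = "female" if rng.random() < params.female_fraction[col] else "male"
        race = _RACES[rng.choice(len(_RACES), p=_RACE_P)]
        comorbidities = {c for c, prev in params.comorbidity_prevalences.items()
                         if rng.random() < prev[col]}
        if "pneumonia" in comorbidities:
            source = "pneumonia"
        else:
            source = _NON_PNEUMONIA_SOURCES[
                rng.choice(len(_NON_PNEUMONIA_SOURCES), p=_NON_PNEUMONIA_P)]

        has_infection = rng.random() >= params.non_infection_fraction
        direct_icu = (not is_case) and rng.random() < params.direct_icu_fraction
        care_limits = rng.random() < params.care_limits_fraction

        # --- latent severity ------------------------------------------------
        drift_start = tte - params.drift_onset if is_case else np.inf
        s0 = float(rng.exponential(params.baseline_severity_scale))
        ramp_scale = float(rng.lognormal(0.0, params.case_severity_sigma)) if is_case else 0.0
        k = params.component_weight_shape

        def severity(hours: np.ndarray) -> np.ndarray:
            if not is_case or params.drift_effect == 0:
                return np.full_like(hours, s0, dtype=float)
            into = np.clip(hours - drift_start, 0.0, params.drift_onset)
            return s0 + ramp_scale * params.drift_effect * into / 12.0

        all_components = _VITAL_COMPONENTS + _PANEL_ANALYTES + _ABG_ANALYTES
        person = {comp: float(rng.normal(0.0, 0.4 * normals[comp]["sd"]))
                  for comp in all_components}
        comp_weight = {comp: float(rng.gamma(k, 1.0 / k)) for comp in all_components}

        def drifted(comp: str, hours: np.ndarray) -> np.ndarray:
            info = normals[comp]
            sd = info["sd"]
            base = info["normal"] + person[comp]
            noise = rng.normal(0.0, 0.92 * sd, size=hours.shape) if sd > 0 else 0.0
            sign = 1.0 if info["worse"] == "high" else -1.0
            weight = comp_weight[comp] * params.drift_overrides.get(comp, 1.0)
            vals = base + noise + sign * weight * severity(hours) * sd
            return np.clip(vals, info["lo"], info["hi"])

        # --- observation schedule with per-window availability ---------------
        def kept(hours: np.ndarray, availability: float) -> np.ndarray:
            anchor = tte if is_case else 0.0
            block = np.floor(np.abs(anchor - hours) / 12.0).astype(int)
            keep = np.ones_like(hours, dtype=bool)
            for b in np.unique(block):
                if rng.random() > availability:
                    keep[block == b] = False
            return keep

        vital_hours = np.arange(0.25, los, params.vitals_interval)
        vital_hours = np.clip(vital_hours + rng.uniform(-0.2, 0.2, size=vital_hours.shape),
                              0.0, los)
        vital_keep = kept(vital_hours, params.vitals_availability)
        sev = severity(vital_hours)
        vital_values = {comp: drifted(comp, vital_hours) for comp in _VITAL_COMPONENTS}
        vitals = []
        for j, h in enumerate(vital_hours):
            if not vital_keep[j]:
                continue
            s = float(sev[j])
            suppl = s > _O2_CUT
            vitals.append(VitalObservation(
                timestamp=admission + timedelta(hours=float(h)),
                heart_rate=float(vital_values["heart_rate"][j]),
                respiratory_rate=float(vital_values["respiratory_rate"][j]),
                systolic_bp=float(vital_values["systolic_bp"][j]),
                diastolic_bp=float(vital_values["diastolic_bp"][j]),
                temperature=float(vital_values["temperature"][j]),
                spo2=float(vital_values["spo2"][j]),
                supplemental_o2=suppl,
                fio2=0.32 if suppl else 0.21,
                avpu=_avpu_from_severity(s),
            ))

        lab_hours = np.arange(1.0, los, params.labs_interval)
        lab_hours = np.clip(lab_hours + rng.uniform(-0.5, 0.5, size=lab_hours.shape), 0.0, los)
        lab_keep = kept(lab_hours, params.labs_availability)
        has_abg = rng.random() < params.abg_fraction
        analytes = _PANEL_ANALYTES + (_ABG_ANALYTES if has_abg else ())
        lab_values = {a: drifted(a, lab_hours) for a in analytes}
        labs = []
        for j, h in enumerate(lab_hours):
            if not lab_keep[j]:
                continue
            t = admission + timedelta(hours=float(h))
            for a in analytes:
                labs.append(LabObservation(timestamp=t, analyte=a,
                                           value=float(lab_values[a][j])))

        record = PatientRecord(
            patient_id=pid, admission_time=admission, discharge_time=discharge,
            age=age, sex=sex, race=race, comorbidities=comorbidities,
            infection_source=source, has_infection=has_infection,
            event_times=event_times, care_limits=care_limits,
            direct_icu_admit=direct_icu, vitals=vitals, labs=labs,
            meta={"synthetic": True, "is_case": is_case,
                  "time_to_event": None if not is_case else float(tte),
                  "drift_onset_used": None if not is_case else float(params.drift_onset),
                  "seed": params.seed},
        )
        records.append(record)
    return records


def ground_truth(cohort: list) -> pd.DataFrame:
    """Ground-truth table for a generated cohort.

    One row per patient with ``is_case`` (any qualifying event present),
    the earliest event time, and the drift onset used.  Refuses cohorts
    lacking generator provenance.
    """
    rows = []
    for record in cohort:
        if not record.meta.get("synthetic"):
            raise ValueError(
                f"{record.patient_id}: not a generated record (no provenance metadata)")
        event_time = min(record.event_times.values()) if record.event_times else None
        rows.append({
            "patient_id": record.patient_id,
            "is_case": record.is_case,
            "event_time": event_time,
            "drift_onset_used": record.meta.get("drift_onset_used"),
        })
    return pd.DataFrame(rows)
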