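"""Domain records for ward admissions and the parameters of the synthetic cohort.

All time intervals are hours; timestamps are timezone-naive ``datetime``.
Laboratory analytes use a controlled vocabulary (:data:`ANALYTES`) with one
canonical unit per analyte, documented in the shared normal-values fixture.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

#: Canonical laboratory analyte vocabulary (canonical units are documented in
#: the normal-values fixture shipped with the package).
ANALYTES = (
    "wbc", "platelets", "bilirubin", "creatinine", "bun", "sodium",
    "potassium", "bicarbonate", "hematocrit", "glucose", "albumin",
    "lactate", "band_fraction", "pao2", "paco2", "ph",
)

#: Events that qualify as clinical deterioration; the index time of a case is
#: the earliest of these.
QUALIFYING_EVENTS = ("icu_transfer", "icu_consult", "rapid_response", "death")

AVPU_LEVELS = ("A", "V", "P", "U")

#: Comorbidity / context flags carried on an admission.
COMORBIDITY_FLAGS = (
    "severe_sepsis", "pneumonia", "chf", "chronic_liver_disease",
    "chronic_pulmonary_disease", "chronic_renal_disease", "diabetes",
    "mi", "hiv", "malignancy", "metastatic", "nursing_home",
)


class ParamError(ValueError):
    """Invalid cohort parameter; the message names the offending field."""


@dataclass(frozen=True)
class VitalObservation:
    """One set of vital signs charted at ``timestamp``."""

    timestamp: datetime
    heart_rate: float
    respiratory_rate: float
    systolic_bp: float
    diastolic_bp: float
    temperature: float
    spo2: float
    supplemental_o2: bool = False
    fio2: Optional[float] = None
    avpu: str = "A"

    def validate(self) -> None:
        if not (10 <= self.heart_rate <= 300):
            raise ValueError(f"heart_rate {self.heart_rate} outside plausible range 10-300")
        if not (0 <= self.spo2 <= 100):
            raise ValueError(f"spo2 {self.spo2} outside 0-100")
        if not (2 <= self.respiratory_rate <= 80):
            raise ValueError(f"respiratory_rate {self.respiratory_rate} outside 2-80")
        if not (25 <= self.temperature <= 45):
            raise ValueError(f"temperature {self.temperature} outside 25-45")
        if self.avpu not in AVPU_LEVELS:
            raise ValueError(f"avpu {self.avpu!r} not one of {AVPU_LEVELS}")
        if self.fio2 is not None and not (0.21 <= self.fio2 <= 1.0):
            raise ValueError(f"fio2 {self.fio2} outside 0.21-1.0")


@dataclass(frozen=True)
class LabObservation:
    """One laboratory result: a canonical analyte in its canonical unit."""

    timestamp: datetime
    analyte: str
    value: float

    def validate(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.analyte == "ph":
            if not (6.5 <= self.value <= 8.0):
                raise ValueError(f"ph {self.value} outside 6.5-8.0")
        elif self.value <= 0 and self.analyte != "band_fraction":
            raise ValueError(f"{self.analyte} concentration must be positive, got {self.value}")


@dataclass
class PatientRecord:
    """One hospital admission with its observation streams.

    ``event_times`` holds the timestamps of any qualifying deterioration
    events (``icu_transfer``, ``icu_consult``, ``rapid_response``,
    ``death``); a patient with none of these is a non-case.  ``meta`` is
    generator provenance (ground-truth flags) and is absent on foreign data.
    """

    patient_id: str
    admission_time: datetime
    discharge_time: datetime
    age: int
    sex: str
    race: str
    comorbidities: set = field(default_factory=set)
    infection_source: Optional[str] = None
    has_infection: bool = True
    event_times: dict = field(default_factory=dict)
    care_limits: bool = False
    direct_icu_admit: bool = False
    vitals: list = field(default_factory=list)
    labs: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return any(k in QUALIFYING_EVENTS for k in self.event_times)

    @property
    def los_hours(self) -> float:
        return (self.discharge_time - self.admission_time).total_seconds() / 3600.0

    def validate(self) -> None:
        if self.admission_time >= self.discharge_time:
            raise ValueError(f"{self.patient_id}: admission_time must precede discharge_time")
        for name, t in self.event_times.items():
            if name not in QUALIFYING_EVENTS:
                raise ValueError(f"{self.patient_id}: unknown event {name!r}")
            if t < self.admission_time:
                raise ValueError(f"{self.patient_id}: event {name} precedes admission")
        for obs in self.vitals:
            if not (self.admission_time <= obs.timestamp <= self.discharge_time):
                raise ValueError(f"{self.patient_id}: vital observation outside stay")
            obs.validate()
        for obs in self.labs:
            if not (self.admission_time <= obs.timestamp <= self.discharge_time):
                raise ValueError(f"{self.patient_id}: lab observation outside stay")
            obs.validate()


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParamError(f"{name} must be in [0, 1], got {value}")


@dataclass
class CohortParams:
    """Parameters of the synthetic ward cohort generator.

    Defaults emulate the structure of an ER-admitted infection cohort on
    general wards: ~6% of admissions deteriorate, median time from admission
    to deterioration 32 h (log-normal), vitals charted every 6 h with >96%
    per-window availability, metabolic panels every 12 h with >93%
    availability, arterial blood gases in ~30% of patients, and case
    physiology drifting toward derangement over the final 48 h before the
    event at ~0.5 baseline SD per 12 h per component, on top of a
    heterogeneous static baseline illness severity shared with controls.
    """

    n_admissions: int = 656
    case_fraction: float = 328 / 5188
    median_time_to_event: float = 32.0
    tte_sigma: float = 1.7
    los_median: float = 96.0
    los_sigma: float = 0.9
    vitals_availability: float = 0.97
    labs_availability: float = 0.94
    abg_fraction: float = 0.30
    drift_onset: float = 48.0
    drift_effect: float = 0.5
    baseline_severity_scale: float = 0.8
    case_severity_sigma: float = 0.5
    component_weight_shape: float = 2.0
    vitals_interval: float = 6.0
    labs_interval: float = 12.0
    n_days: int = 121
    start_date: str = "2009-12-01"
    # Multinomial-with-overlap event mix (ICU transfer / consult or rapid
    # response / death) matching a 142:200:110 composition among 328 cases.
    p_icu_transfer: float = 142 / 328
    p_rapid_response: float = 200 / 328
    p_death: float = 110 / 328
    # Per-condition prevalence among cases / controls (baseline imbalance).
    comorbidity_prevalences: dict = field(default_factory=lambda: {
        "severe_sepsis": (0.76, 0.32),
        "pneumonia": (0.42, 0.26),
        "chf": (0.38, 0.30),
        "chronic_liver_disease": (0.25, 0.23),
        "chronic_pulmonary_disease": (0.38, 0.41),
        "chronic_renal_disease": (0.27, 0.25),
        "diabetes": (0.43, 0.41),
        "mi": (0.17, 0.15),
        "hiv": (0.05, 0.06),
        "malignancy": (0.23, 0.19),
        "metastatic": (0.09, 0.07),
        "nursing_home": (0.15, 0.08),
    })
    female_fraction: tuple = (0.53, 0.63)  # cases, controls
    age_mean: tuple = (66.0, 63.0)
    age_sd: float = 16.0
    # Fractions exercised by the inclusion/exclusion stage; the default
    # cohort is already post-exclusion, so these are zero.
    direct_icu_fraction: float = 0.0
    care_limits_fraction: float = 0.0
    non_infection_fraction: float = 0.0
    baseline_overrides: dict = field(default_factory=dict)
    drift_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_admissions < 2:
            raise ParamError(f"n_admissions must be >= 2, got {self.n_admissions}")
        if self.median_time_to_event <= 0:
            raise ParamError(f"median_time_to_event must be > 0, got {self.median_time_to_event}")
        if self.los_median <= 0:
            raise ParamError(f"los_median must be > 0, got {self.los_median}")
        for name in ("case_fraction", "vitals_availability", "labs_availability",
                     "abg_fraction", "direct_icu_fraction", "care_limits_fraction",
                     "non_infection_fraction"):
            _check_proportion(name, getattr(self, name))
        for name in ("p_icu_transfer", "p_rapid_response", "p_death"):
            _check_proportion(name, getattr(self, name))
        if self.drift_onset <= 0:
            raise ParamError(f"drift_onset must be > 0, got {self.drift_onset}")
        if self.drift_effect < 0:
            raise ParamError(f"drift_effect must be >= 0, got {self.drift_effect}")
        if self.baseline_severity_scale < 0:
            raise ParamError("baseline_severity_scale must be >= 0")
        if self.component_weight_shape <= 0:
            raise ParamError("component_weight_shape must be > 0")
        if self.vitals_interval <= 0 or self.labs_interval <= 0:
            raise ParamError("observation intervals must be > 0")
        for cond, (pc, pn) in self.comorbidity_prevalences.items():
            _check_proportion(f"comorbidity_prevalences[{cond}] case", pc)
            _check_proportion(f"comorbidity_prevalences[{cond}] control", pn)
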