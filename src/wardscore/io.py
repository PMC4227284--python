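"""Cohort file round-trip: a patients CSV, a long-format observations CSV,
and a JSON sidecar with the generator params and seed.

Timestamps are ISO-8601; intervals are hours.  The observations file is one
row per (patient, timestamp, component): vitals components expand to one
row each (including ``supplemental_o2``, ``fio2`` and ``avpu``), labs to
one row per analyte.
"""
from __future__ import annotations

import dataclasses
import json
from datetime import datetime
from pathlib import Path

import pandas as pd

from .records import CohortParams, LabObservation, PatientRecord, VitalObservation, ANALYTES

__all__ = ["write_cohort", "read_cohort"]

_VITAL_FIELDS = ("heart_rate", "respiratory_rate", "systolic_bp",
                 "diastolic_bp", "temperature", "spo2", "supplemental_o2",
                 "fio2", "avpu")
_EVENTS = ("icu_transfer", "icu_consult", "rapid_response", "death")


def write_cohort(records: list, out_dir, params: CohortParams | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    patient_rows = []
    obs_rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "admission_time": r.admission_time.isoformat(),
            "discharge_time": r.discharge_time.isoformat(),
            "age": r.age, "sex": r.sex, "race": r.race,
            "comorbidities": ";".join(sorted(r.comorbidities)),
            "infection_source": r.infection_source or "",
            "has_infection": int(r.has_infection),
            "care_limits": int(r.care_limits),
            "direct_icu_admit": int(r.direct_icu_admit),
            "meta": json.dumps(r.meta, default=str) if r.meta else "",
        }
        for e in _EVENTS:
            row[f"event_{e}"] = r.event_times[e].isoformat() if e in r.event_times else ""
        patient_rows.append(row)

        for v in r.vitals:
            ts = v.timestamp.isoformat()
            for f in _VITAL_FIELDS:
                value = getattr(v, f)
                if value is None:
                    continue
                if f == "supplemental_o2":
                    value = int(value)
                obs_rows.append((r.patient_id, ts, "vital", f, str(value)))
        for lab in r.labs:
            obs_rows.append((r.patient_id, lab.timestamp.isoformat(), "lab",
                             lab.analyte, repr(lab.value)))

    pd.DataFrame(patient_rows).to_csv(out / "patients.csv", index=False)
    pd.DataFrame(obs_rows, columns=["patient_id", "timestamp", "kind", "name", "value"]
                 ).to_csv(out / "observations.csv", index=False)
    sidecar = {"params": dataclasses.asdict(params) if params else None,
               "n_records": len(records)}
    (out / "params.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return out


def params_from_dict(raw: dict) -> CohortParams:
    raw = dict(raw)
    for key in ("female_fraction", "age_mean"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "comorbidity_prevalences" in raw:
        raw["comorbidity_prevalences"] = {
            k: tuple(v) for k, v in raw["comorbidity_prevalences"].items()}
    known = {f.name for f in dataclasses.fields(CohortParams)}
    return CohortParams(**{k: v for k, v in raw.items() if k in known})


def read_cohort(in_dir) -> tuple:
    """Read a cohort directory back into records; returns (records, params)."""
    src = Path(in_dir)
    patients = pd.read_csv(src / "patients.csv", keep_default_na=False)
    obs = pd.read_csv(src / "observations.csv", keep_default_na=False)

    by_patient: dict = {pid: g for pid, g in obs.groupby("patient_id")}
    records = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        vitals, labs = [], []
        g = by_patient.get(pid)
        if g is not None:
            vit = g[g["kind"] == "vital"]
            for ts, vg in vit.groupby("timestamp", sort=True):
                fields = dict(zip(vg["name"], vg["value"]))
                vitals.append(VitalObservation(
                    timestamp=datetime.fromisoformat(ts),
                    heart_rate=float(fields["heart_rate"]),
                    respiratory_rate=float(fields["respiratory_rate"]),
                    systolic_bp=float(fields["systolic_bp"]),
                    diastolic_bp=float(fields["diastolic_bp"]),
                    temperature=float(fields["temperature"]),
                    spo2=float(fields["spo2"]),
                    supplemental_o2=bool(int(fields.get("supplemental_o2", "0"))),
                    fio2=float(fields["fio2"]) if "fio2" in fields else None,
                    avpu=fields.get("avpu", "A"),
                ))
            for _, lrow in g[g["kind"] == "lab"].iterrows():
                if lrow["name"] not in ANALYTES:
                    raise ValueError(f"unknown analyte {lrow['name']!r} in observations file")
                labs.append(LabObservation(
                    timestamp=datetime.fromisoformat(lrow["timestamp"]),
                    analyte=lrow["name"], value=float(lrow["value"])))
        labs.sort(key=lambda o: (o.timestamp, o.analyte))

        event_times = {e: datetime.fromisoformat(row[f"event_{e}"])
                       for e in _EVENTS if row.get(f"event_{e}", "")}
        meta = json.loads(row["meta"]) if row.get("meta", "") else {}
        records.append(PatientRecord(
            patient_id=pid,
            admission_time=datetime.fromisoformat(row["admission_time"]),
            discharge_time=datetime.fromisoformat(row["discharge_time"]),
            age=int(row["age"]), sex=row["sex"], race=row["race"],
            comorbidities=set(c for c in str(row["comorbidities"]).split(";") if c),
            infection_source=row["infection_source"] or None,
            has_infection=bool(int(row["has_infection"])),
            event_times=event_times,
            care_limits=bool(int(row["care_limits"])),
            direct_icu_admit=bool(int(row["direct_icu_admit"])),
            vitals=vitals, labs=labs, meta=meta,
        ))

    sidecar = json.loads((src / "params.json").read_text())
    params = params_from_dict(sidecar["params"]) if sidecar.get("params") else None
    return records, params
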