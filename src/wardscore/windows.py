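"""Pre-index time windows: observation binning, worst-value selection, and
the carry-back / assume-normal imputation cascade.

Scores are evaluated in four windows counting back from the index time
(0-12, 12-24, 24-48 and 48-72 h by default).  Within a window the single
worst value of each component is used, where "worst" means the value earning
the most points under the component's band table for the score at hand.  A
component missing from a window is filled from the nearest window that is
*earlier in clock time* (farther from the index) and actually has a
measured value; failing that it is assumed normal.  Carrying only from
farther-from-index windows means no deterioration signal ever leaks
backward in time.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional

from .records import AVPU_LEVELS, COMORBIDITY_FLAGS, PatientRecord
from .scores import (ComponentDef, FixtureError, ScoreDefinition, ScoreError,
                     Snapshot, avpu_to_gcs, load_all_definitions,
                     load_normal_values)

__all__ = [
    "WindowSpec", "DEFAULT_WINDOWS", "assign_windows", "worst_value",
    "impute_cascade", "windowed_snapshots", "score_patient", "static_context",
]


@dataclass(frozen=True)
class WindowSpec:
    """Ordered pre-index windows ``(label, start, end)`` in hours before index.

    Windows are half-open ``[start, end)``, contiguous, and listed nearest
    the index first.
    """

    windows: tuple = (("W1", 0.0, 12.0), ("W2", 12.0, 24.0),
                      ("W3", 24.0, 48.0), ("W4", 48.0, 72.0))

    def __post_init__(self):
        prev_end = 0.0
        for label, start, end in self.windows:
            if start != prev_end:
                raise ValueError(f"window {label}: expected start {prev_end}, got {start}")
            if end <= start:
                raise ValueError(f"window {label}: empty interval [{start}, {end})")
            prev_end = end

    @property
    def labels(self) -> list:
        return [w[0] for w in self.windows]

    def locate(self, hours_before: float) -> Optional[str]:
        for label, start, end in self.windows:
            if start <= hours_before < end:
                return label
        return None


DEFAULT_WINDOWS = WindowSpec()

#: Aggregation rule for time-varying components consumed by hooks (no band
#: table of their own in a given score): which extreme is worse.
_AUX_WORSE = {
    "fio2": "high", "pao2": "low", "paco2": "high", "spo2": "low",
    "respiratory_rate": "high", "systolic_bp": "low", "map": "low",
    "pao2_fio2_ratio": "low", "heart_rate": "high",
}

_VITAL_FIELDS = ("heart_rate", "respiratory_rate", "systolic_bp",
                 "diastolic_bp", "temperature", "spo2")


def _observation_stream(record: PatientRecord):
    """Yield ``(timestamp, component, value)`` including derived components
    (MAP from SBP/DBP, PaO2/FiO2 ratio from blood gas + concurrent FiO2)."""
    vitals = sorted(record.vitals, key=lambda o: o.timestamp)
    for obs in vitals:
        for name in _VITAL_FIELDS:
            yield obs.timestamp, name, getattr(obs, name)
        yield obs.timestamp, "map", (obs.systolic_bp + 2.0 * obs.diastolic_bp) / 3.0
        yield obs.timestamp, "avpu", obs.avpu
        yield obs.timestamp, "supplemental_o2", bool(obs.supplemental_o2)
        fio2 = obs.fio2 if obs.fio2 is not None else 0.21
        yield obs.timestamp, "fio2", fio2

    def fio2_at(t: datetime) -> float:
        current = 0.21
        for obs in vitals:
            if obs.timestamp > t:
                break
            if obs.fio2 is not None:
                current = obs.fio2
            elif not obs.supplemental_o2:
                current = 0.21
        return current

    for lab in record.labs:
        yield lab.timestamp, lab.analyte, lab.value
        if lab.analyte == "pao2":
            yield lab.timestamp, "pao2_fio2_ratio", lab.value / fio2_at(lab.timestamp)


def assign_windows(record: PatientRecord, index_time: datetime,
                   spec: WindowSpec = DEFAULT_WINDOWS):
    """Group a patient's observations into pre-index windows.

    Returns ``(grouped, in_hospital)`` where ``grouped[label]`` is a list of
    ``(hours_before_index, component, value)`` and ``in_hospital[label]``
    says whether the window overlaps the hospital stay.  Observations after
    the index or before admission are excluded.
    """
    if index_time < record.admission_time:
        raise ValueError(f"{record.patient_id}: index time precedes admission")
    admission_to_index = (index_time - record.admission_time).total_seconds() / 3600.0
    grouped = {label: [] for label in spec.labels}
    in_hospital = {label: start < admission_to_index for label, start, _ in spec.windows}
    for t, comp, value in _observation_stream(record):
        if t < record.admission_time or t > index_time:
            continue
        hours_before = (index_time - t).total_seconds() / 3600.0
        label = spec.locate(hours_before)
        if label is not None:
            grouped[label].append((hours_before, comp, value))
    return grouped, in_hospital


def worst_value(observations, component: ComponentDef, normal: Optional[float] = None):
    """The observation earning the most points under a component's band table.

    ``observations`` is a list of ``(value, hours_before_index)``.  Ties on
    points go to the more deranged value (farther in the component's worse
    direction), then to the observation closest to the index time.  An empty
    list signals "missing" and raises, triggering the imputation cascade.
    """
    if not observations:
        raise ScoreError(f"{component.name}: no observations in window")
    if normal is None:
        normal = component.normal_midpoint()

    def extremeness(value: float) -> float:
        if component.direction == "high":
            return value
        if component.direction == "low":
            return -value
        return abs(value - normal)

    best = max(observations,
               key=lambda vh: (component.lookup(float(vh[0])), extremeness(float(vh[0])), -vh[1]))
    return best[0]


def _worst_directional(observations, worse: str):
    """Direction-based worst for components without a band table."""
    if worse == "high":
        return max(observations, key=lambda vh: (vh[0], -vh[1]))[0]
    return min(observations, key=lambda vh: (vh[0], vh[1]))[0]


def _worst_avpu(observations):
    order = {level: i for i, level in enumerate(AVPU_LEVELS)}
    return max(observations, key=lambda vh: (order[vh[0]], -vh[1]))[0]


def impute_cascade(window_values: dict, normals: dict, labels: list,
                   policy: str = "nearest"):
    """Fill missing per-window component values by carry-back, else normal.

    ``window_values[label][component]`` is a measured worst value or ``None``.
    ``labels`` orders windows nearest-to-index first.  A missing value in
    window *w* is carried from the nearest farther-from-index window holding
    a *measured* value (never from another carried value); under
    ``policy='one_step'`` only the adjacent window is consulted.  Otherwise
    the component's documented normal is used.

    Returns ``{label: (values, provenance)}`` with provenance in
    ``{'measured', 'carried', 'normal_default'}``.
    """
    if policy not in ("nearest", "one_step"):
        raise ValueError(f"unknown carry policy {policy!r}")
    out = {}
    for i, label in enumerate(labels):
        values, prov = {}, {}
        for comp, value in window_values[label].items():
            if value is not None:
                values[comp], prov[comp] = value, "measured"
                continue
            carried = None
            farther = labels[i + 1:i + 2] if policy == "one_step" else labels[i + 1:]
            for src in farther:
                if window_values[src].get(comp) is not None:
                    carried = window_values[src][comp]
                    break
            if carried is not None:
                values[comp], prov[comp] = carried, "carried"
            else:
                if comp == "avpu":
                    values[comp] = "A"
                elif comp == "supplemental_o2":
                    values[comp] = False
                else:
                    if comp not in normals:
                        raise FixtureError(f"component {comp!r} missing from normal-values fixture")
                    values[comp] = normals[comp]["normal"]
                prov[comp] = "normal_default"
        out[label] = (values, prov)
    return out


def static_context(record: PatientRecord, extra: Optional[dict] = None) -> dict:
    """Time-invariant snapshot entries: age, comorbidity/context flags, and
    ward defaults (no ventilator, no vasopressors, medical admission)."""
    ctx = {flag: (flag in record.comorbidities) for flag in COMORBIDITY_FLAGS}
    if record.infection_source == "pneumonia":
        ctx["pneumonia"] = True
    ctx.update({
        "age": record.age,
        "admission_type": "medical",
        "mechanical_ventilation": False,
        "vasopressor_level": "none",
        # Functional-status items are not charted for ward patients and
        # score 0 (normal).
        "breathless": False, "abnormal_ecg": False,
        "unable_to_stand": False, "new_stroke": False,
    })
    if extra:
        ctx.update(extra)
    return ctx


def windowed_snapshots(record: PatientRecord, index_time: datetime,
                       definition: ScoreDefinition, *,
                       spec: WindowSpec = DEFAULT_WINDOWS,
                       normals: Optional[dict] = None,
                       policy: str = "nearest",
                       static_extra: Optional[dict] = None):
    """Build one complete scored-ready snapshot per window for one score.

    Returns a list of ``(label, in_hospital, Snapshot)`` in window order
    (nearest the index first).  Worst-value selection is specific to this
    score's band tables; imputation provenance is recorded per component.
    """
    normals = normals if normals is not None else load_normal_values()
    grouped, in_hospital = assign_windows(record, index_time, spec)
    needed = definition.windowed_inputs()
    banded = {c.name: c for c in definition.components}

    window_values = {}
    for label in spec.labels:
        by_comp = {}
        for hours_before, comp, value in grouped[label]:
            if comp in needed:
                by_comp.setdefault(comp, []).append((value, hours_before))
        values = {}
        for comp in needed:
            obs = by_comp.get(comp)
            if not obs:
                values[comp] = None
            elif comp == "avpu":
                values[comp] = _worst_avpu(obs)
            elif comp == "supplemental_o2":
                values[comp] = any(v for v, _ in obs)
            elif comp in banded:
                values[comp] = worst_value(obs, banded[comp],
                                           normal=normals.get(comp, {}).get("normal"))
            else:
                values[comp] = _worst_directional(obs, _AUX_WORSE.get(comp, "high"))
        window_values[label] = values

    filled = impute_cascade(window_values, normals, spec.labels, policy=policy)
    context = static_context(record, static_extra)
    out = []
    for label in spec.labels:
        values, prov = filled[label]
        values = dict(values)
        if "gcs" in needed and "gcs" not in values:
            # GCS is not charted on wards; derive it from the window-worst AVPU.
            avpu = values.get("avpu", "A")
            values["gcs"] = avpu_to_gcs(avpu)
            prov = dict(prov, gcs=prov.get("avpu", "normal_default"))
        snapshot = Snapshot({**context, **values}, provenance=prov)
        out.append((label, in_hospital[label], snapshot))
    return out


def windowed_features(record: PatientRecord, index_time: datetime,
                      definitions: Optional[dict] = None, *,
                      spec: WindowSpec = DEFAULT_WINDOWS,
                      normals: Optional[dict] = None,
                      policy: str = "nearest"):
    """Component-level worst values with provenance, one row per
    (score, window, component); suitable for a long-format CSV."""
    definitions = definitions or load_all_definitions()
    normals = normals if normals is not None else load_normal_values()
    rows = []
    for name in sorted(definitions):
        definition = definitions[name]
        windowed = definition.windowed_inputs()
        for label, in_hosp, snap in windowed_snapshots(
                record, index_time, definition, spec=spec, normals=normals, policy=policy):
            for comp in sorted(windowed):
                rows.append({"patient_id": record.patient_id, "window": label,
                             "score": name, "component": comp,
                             "value": snap.values.get(comp),
                             "provenance": snap.provenance.get(comp, "static"),
                             "in_hospital": in_hosp})
    return rows


def load_window_config(path) -> dict:
    """Read a windows-config JSON: window boundaries and carry policy.

    Format: ``{"windows": [["W1", 0, 12], ...], "carry": "nearest"}``;
    both keys optional.
    """
    import json
    from pathlib import Path
    raw = json.loads(Path(path).read_text())
    spec = DEFAULT_WINDOWS
    if "windows" in raw:
        spec = WindowSpec(windows=tuple((str(l), float(a), float(b))
                                        for l, a, b in raw["windows"]))
    return {"spec": spec, "policy": raw.get("carry", "nearest")}


def score_patient(record: PatientRecord, index_time: datetime,
                  definitions: Optional[dict] = None, *,
                  spec: WindowSpec = DEFAULT_WINDOWS,
                  normals: Optional[dict] = None,
                  policy: str = "nearest"):
    """Score one patient under all requested definitions in all windows.

    Returns a list of row dicts (patient_id, window, score, total,
    in_hospital, n_defaulted) suitable for a long-format DataFrame.
    """
    from .scores import compute_score
    definitions = definitions or load_all_definitions()
    normals = normals if normals is not None else load_normal_values()
    rows = []
    for name in sorted(definitions):
        definition = definitions[name]
        for label, in_hosp, snapshot in windowed_snapshots(
                record, index_time, definition, spec=spec, normals=normals, policy=policy):
            result = compute_score(definition, snapshot)
            rows.append({
                "patient_id": record.patient_id, "window": label, "score": name,
                "total": result.total, "in_hospital": in_hosp,
                "n_defaulted": len(result.defaulted_components),
            })
    return rows
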