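"""End-to-end analysis pipeline on a ward cohort.

Chains the stages: eligibility -> case identification -> matched-control
sampling -> windowed scoring of every paired subject -> time-resolved AUC
table, SOFA decision-rule models (earliest / peak / earliest-or-delta),
adjusted odds ratios, score trajectories, and a baseline characteristics
table.  The deterioration endpoint uses all matched pairs; the mortality
endpoint reruns the identical machinery on the subset of pairs whose case
died in hospital.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import design, evaluation
from .records import PatientRecord
from .scores import load_all_definitions, load_normal_values
from .windows import DEFAULT_WINDOWS, WindowSpec, score_patient

__all__ = ["match_cohort", "score_pairs", "sofa_model_inputs", "run_analysis"]

_RULE_COVARIATES = ("age", "female", "severe_sepsis", "pneumonia", "chf")


def match_cohort(records: list, seed: int = 0):
    """Eligibility + case identification + control sampling.

    Returns ``(eligible, cases, pairs, info)`` where ``info`` carries the
    exclusion counts and the number of unmatched cases.
    """
    eligible, exclusions = design.build_cohort(records)
    cases = design.identify_cases(eligible)
    pairs, n_dropped = design.sample_controls(cases, eligible, seed=seed)
    info = {"exclusions": exclusions, "n_cases": len(cases),
            "n_pairs": len(pairs), "n_unmatched_cases": n_dropped}
    return eligible, cases, pairs, info


def score_pairs(records: list, pairs: list, *, definitions: Optional[dict] = None,
                spec: WindowSpec = DEFAULT_WINDOWS, policy: str = "nearest") -> pd.DataFrame:
    """Windowed scores for every subject in the matched pairs.

    Long format: patient_id, role (case/control), pair index, window,
    score, total, in_hospital.
    """
    definitions = definitions or load_all_definitions()
    normals = load_normal_values()
    by_id = {r.patient_id: r for r in records}
    frames = []
    for k, pair in enumerate(pairs):
        for role, pid, index_time in (("case", pair.case_id, pair.case_index_time),
                                      ("control", pair.control_id, pair.control_index_time)):
            rows = score_patient(by_id[pid], index_time, definitions,
                                 spec=spec, normals=normals, policy=policy)
            for row in rows:
                row.update(role=role, pair=k)
            frames.extend(rows)
    return pd.DataFrame(frames)


def sofa_model_inputs(scores_df: pd.DataFrame, *, score: str = "SOFA",
                      spec: WindowSpec = DEFAULT_WINDOWS) -> pd.DataFrame:
    """Per-subject inputs of the three SOFA models.

    earliest = score in the farthest-from-index window the patient was in
    hospital for; latest = score in the window nearest the index; peak = max
    over in-hospital windows; delta = latest - earliest.  Patients in
    hospital for a single window have delta = 0 by construction.
    """
    order = {label: i for i, label in enumerate(spec.labels)}  # W1 -> 0 (nearest)
    sub = scores_df[(scores_df["score"] == score) & scores_df["in_hospital"]]
    rows = []
    for pid, g in sub.groupby("patient_id", sort=True):
        g = g.assign(_o=g["window"].map(order)).sort_values("_o")
        rows.append({
            "patient_id": pid,
            "role": g["role"].iloc[0] if "role" in g else "",
            "latest": float(g["total"].iloc[0]),
            "earliest": float(g["total"].iloc[-1]),
            "peak": float(g["total"].max()),
            "delta": float(g["total"].iloc[0] - g["total"].iloc[-1]),
            "n_windows": len(g),
        })
    return pd.DataFrame(rows)


def _labels_and_covariates(records_by_id: dict, scores_df: pd.DataFrame):
    subjects = scores_df[["patient_id", "role"]].drop_duplicates()
    labels = {row.patient_id: row.role == "case" for row in subjects.itertuples()}
    cov_rows = []
    for pid in subjects["patient_id"]:
        r = records_by_id[pid]
        cov_rows.append({
            "patient_id": pid, "age": r.age,
            "female": 1.0 if r.sex == "female" else 0.0,
            "severe_sepsis": 1.0 if "severe_sepsis" in r.comorbidities else 0.0,
            "pneumonia": 1.0 if ("pneumonia" in r.comorbidities
                                 or r.infection_source == "pneumonia") else 0.0,
            "chf": 1.0 if "chf" in r.comorbidities else 0.0,
        })
    return labels, pd.DataFrame(cov_rows).set_index("patient_id")


def _sofa_models_table(inputs: pd.DataFrame, labels: dict,
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """Three-model SOFA comparison: earliest-threshold, peak-threshold, and
    the earliest-or-delta rule, each with Youden-optimal thresholds."""
    y = np.array([labels[pid] for pid in inputs["patient_id"]], dtype=bool)
    cov = covariates.loc[inputs["patient_id"]].reset_index(drop=True)
    out = []

    def row(model, threshold_desc, positive):
        perf = evaluation.evaluate_rule(positive, y)
        try:
            or_adj, or_adj_ci = evaluation.adjusted_or(positive, y, cov)
        except ValueError:
            or_adj, or_adj_ci = np.nan, (np.nan, np.nan)
        out.append({
            "model": model, "threshold": threshold_desc,
            "sensitivity": perf.sensitivity, "specificity": perf.specificity,
            "youden": perf.youden, "or_crude": perf.or_crude,
            "or_lo": perf.or_ci[0], "or_hi": perf.or_ci[1],
            "or_adjusted": or_adj, "or_adj_lo": or_adj_ci[0], "or_adj_hi": or_adj_ci[1],
        })

    t_e, _ = evaluation.youden_threshold(inputs["earliest"], y)
    row("earliest", f"earliest >= {t_e:g}", inputs["earliest"].to_numpy() >= t_e)
    t_p, _ = evaluation.youden_threshold(inputs["peak"], y)
    row("peak", f"peak >= {t_p:g}", inputs["peak"].to_numpy() >= t_p)
    rule, _ = evaluation.derive_delta_rule(inputs["earliest"], inputs["delta"], y)
    row("earliest_or_delta",
        f"earliest >= {rule.theta_base:g} or delta > {rule.theta_delta:g}",
        evaluation.apply_rule(rule, inputs["earliest"], inputs["delta"]))
    return pd.DataFrame(out)


def run_analysis(records: list, *, seed: int = 0, endpoint: str = "deterioration",
                 definitions: Optional[dict] = None,
                 spec: WindowSpec = DEFAULT_WINDOWS,
                 with_trajectories: bool = True) -> dict:
    """Full pipeline on a cohort of :class:`PatientRecord`.

    Returns a dict with the matched pairs, the long score table, the
    score-by-window AUC table, the SOFA three-model table, the trajectory
    fit (optional), and a baseline characteristics table.
    """
    if endpoint not in ("deterioration", "mortality"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    eligible, cases, pairs, info = match_cohort(records, seed=seed)
    if endpoint == "mortality":
        by_id = {r.patient_id: r for r in eligible}
        pairs = [p for p in pairs if "death" in by_id[p.case_id].event_times]
    if not pairs:
        raise ValueError(f"no matched pairs for endpoint {endpoint!r}")
    scores_df = score_pairs(records, pairs, definitions=definitions, spec=spec)
    by_id = {r.patient_id: r for r in records}
    labels, covariates = _labels_and_covariates(by_id, scores_df)

    auc_table = evaluation.auc_by_window(scores_df, labels)
    inputs = sofa_model_inputs(scores_df, spec=spec)
    sofa_models = _sofa_models_table(inputs, labels, covariates)

    trajectories = None
    if with_trajectories:
        sofa_long = scores_df[(scores_df["score"] == "SOFA")
                              & scores_df["in_hospital"]].copy()
        sofa_long["group"] = sofa_long["patient_id"].map(labels).astype(float)
        cov = covariates.loc[sofa_long["patient_id"]].reset_index(drop=True)
        sofa_long = pd.concat([sofa_long.reset_index(drop=True), cov], axis=1)
        trajectories = evaluation.fit_trajectories(
            sofa_long, covariates=list(_RULE_COVARIATES),
            windows_time_order=list(reversed(spec.labels)))

    case_ids = {p.case_id for p in pairs}
    control_ids = {p.control_id for p in pairs}
    base_cases = covariates.loc[sorted(case_ids)].reset_index(drop=True)
    base_controls = covariates.loc[sorted(control_ids)].reset_index(drop=True)
    baseline = evaluation.summarize_baseline(base_cases, base_controls)

    return {"info": info, "pairs": pairs, "scores": scores_df,
            "auc_table": auc_table, "sofa_inputs": inputs,
            "sofa_models": sofa_models, "trajectories": trajectories,
            "baseline": baseline, "labels": labels}
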