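"""Discrimination analysis, decision-rule derivation, and score trajectories.

The discrimination machinery is time-resolved: each score is evaluated per
pre-index window against the case/control label, giving an AUC with a
DeLong variance and 95% CI.  Correlated AUCs on the same subjects are
compared with the paired DeLong test; AUCs on different subject sets with
an ad hoc z-test that assumes a correlation of 0.5 between the estimates.

Decision rules are derived by exhaustive search: a single-threshold rule
maximizing the Youden index (J = sensitivity + specificity - 1), and a
two-threshold rule "earliest score >= theta_base OR delta score >
theta_delta" searched over the full integer grid of observed values.  Rule
performance is summarized as sensitivity, specificity, the crude 2x2 odds
ratio with a Woolf CI, and a covariate-adjusted odds ratio from
unconditional logistic regression.

Score trajectories over the pre-index windows are modeled with a linear
mixed-effects model (patient-level random intercept, optionally a random
slope on window time, chosen by AIC) with fixed effects for group, window,
their interaction, and baseline covariates; within-group consecutive-window
contrasts localize when case scores begin to rise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult", "RuleSpec", "RulePerformance", "TrajectoryFit",
    "auc_delong", "delong_paired_test", "adhoc_z_unequal", "auc_by_window",
    "youden_threshold", "derive_delta_rule", "evaluate_rule", "adjusted_or",
    "fit_trajectories", "summarize_baseline", "discrimination_label",
]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    variance: float
    ci95: tuple
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class RuleSpec:
    """Two-threshold decision rule: positive iff earliest score >= theta_base
    or delta score > theta_delta."""

    theta_base: float
    theta_delta: float


@dataclass
class RulePerformance:
    sensitivity: float
    specificity: float
    youden: float
    counts: dict               # TP, FN, FP, TN
    or_crude: Optional[float] = None
    or_ci: Optional[tuple] = None
    haldane_corrected: bool = False
    or_adjusted: Optional[float] = None
    or_adjusted_ci: Optional[tuple] = None


@dataclass
class TrajectoryFit:
    fixed_effects: pd.Series
    aic: float
    re_structure: str
    contrasts: pd.DataFrame
    interaction_p: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def discrimination_label(auc: float) -> str:
    """Qualitative discrimination tag: >=0.70 acceptable, >=0.80 excellent."""
    if auc >= 0.80:
        return "excellent"
    if auc >= 0.70:
        return "acceptable"
    return "poor"


# --- DeLong AUC machinery ---------------------------------------------------

def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes (cases and controls) must be present")
    return labels


def _delong_structural(pos: np.ndarray, neg: np.ndarray):
    """AUC plus the DeLong structural components V10 (cases) and V01 (controls)."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return auc, v10, v01


def auc_delong(scores, labels) -> ROCResult:
    """Mann-Whitney AUC (ties counted 1/2) with DeLong variance and 95% CI."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    auc, v10, v01 = _delong_structural(pos, neg)
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return ROCResult(auc=float(auc), variance=float(var),
                     ci95=(max(0.0, auc - half), min(1.0, auc + half)),
                     n_cases=m, n_controls=n)


def delong_paired_test(scores_a, scores_b, labels):
    """Paired DeLong test for two correlated AUCs on the same subjects.

    Returns ``(z, p)`` with a two-sided p-value; identical or
    monotone-equivalent score vectors give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(scores_a) != len(scores_b):
        raise ValueError("paired score vectors must have equal length")
    labels = _check_labels(labels)
    if len(labels) != len(scores_a):
        raise ValueError("labels length must match the score vectors")

    auc_a, v10_a, v01_a = _delong_structural(scores_a[labels], scores_a[~labels])
    auc_b, v10_b, v01_b = _delong_structural(scores_b[labels], scores_b[~labels])
    m, n = labels.sum(), (~labels).sum()
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ s @ contrast)
    diff = auc_a - auc_b
    if var <= 0:
        return (0.0, 1.0) if np.isclose(diff, 0.0) else (np.inf * np.sign(diff), 0.0)
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def adhoc_z_unequal(auc_a: float, var_a: float, auc_b: float, var_b: float,
                    rho: float = 0.5):
    """z-test for AUCs from different subject sets assuming correlation rho.

    ``z = (auc_a - auc_b) / sqrt(var_a + var_b - 2 rho sqrt(var_a var_b))``.
    """
    if var_a <= 0 or var_b <= 0:
        raise ValueError("variances must be positive")
    denom_sq = var_a + var_b - 2.0 * rho * np.sqrt(var_a * var_b)
    if denom_sq <= 0:
        raise ValueError(f"non-positive variance of the difference ({denom_sq})")
    z = (auc_a - auc_b) / np.sqrt(denom_sq)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def auc_by_window(scores_df: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Per-(score, window) ROC table.

    ``scores_df`` is long format with columns ``patient_id``, ``window``,
    ``score``, ``total`` and ``in_hospital``; ``labels`` maps patient_id to
    case status.  Subjects whose window falls outside their hospital stay
    are excluded from that window's ROC.  A (score, window) cell with a
    single class is flagged (``auc`` = NaN, ``note`` set), not dropped
    silently.
    """
    rows = []
    for (score, window), group in scores_df.groupby(["score", "window"], sort=True):
        group = group[group["in_hospital"]]
        y = np.array([labels[pid] for pid in group["patient_id"]], dtype=bool)
        row = {"score": score, "window": window,
               "n_cases": int(y.sum()), "n_controls": int((~y).sum())}
        try:
            roc = auc_delong(group["total"].to_numpy(dtype=float), y)
            row.update(auc=roc.auc, variance=roc.variance,
                       ci_lo=roc.ci95[0], ci_hi=roc.ci95[1],
                       discrimination=discrimination_label(roc.auc), note="")
        except ValueError as exc:
            row.update(auc=np.nan, variance=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                       discrimination="", note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


# --- thresholds and rules ----------------------------------------------------

def _confusion(positive: np.ndarray, labels: np.ndarray) -> dict:
    return {
        "TP": int((positive & labels).sum()),
        "FN": int((~positive & labels).sum()),
        "FP": int((positive & ~labels).sum()),
        "TN": int((~positive & ~labels).sum()),
    }


def youden_threshold(scores, labels):
    """Best single ">= t" threshold by the Youden index.

    Scans every observed score value; ties on J go to the lowest threshold.
    Returns ``(threshold, RulePerformance)``.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    best = None
    for t in np.unique(scores):
        positive = scores >= t
        counts = _confusion(positive, labels)
        sens = counts["TP"] / (counts["TP"] + counts["FN"])
        spec = counts["TN"] / (counts["TN"] + counts["FP"])
        j = sens + spec - 1.0
        if best is None or j > best[1].youden + 1e-12:
            best = (float(t), RulePerformance(sensitivity=sens, specificity=spec,
                                              youden=j, counts=counts))
    return best


def evaluate_rule(positive, labels) -> RulePerformance:
    """2x2 performance of a rule indicator: sensitivity, specificity, and the
    crude odds ratio with a Woolf 95% CI (Haldane-Anscombe 0.5 correction on
    a zero cell, flagged in the output)."""
    labels = _check_labels(labels)
    positive = np.asarray(positive).astype(bool)
    counts = _confusion(positive, labels)
    sens = counts["TP"] / (counts["TP"] + counts["FN"])
    spec = counts["TN"] / (counts["TN"] + counts["FP"])
    a, b, c, d = counts["TP"], counts["FN"], counts["FP"], counts["TN"]
    haldane = 0 in (a, b, c, d)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_crude = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(or_crude * np.exp(-1.959963984540054 * se_log)),
          float(or_crude * np.exp(1.959963984540054 * se_log)))
    return RulePerformance(sensitivity=sens, specificity=spec,
                           youden=sens + spec - 1.0, counts=counts,
                           or_crude=float(or_crude), or_ci=ci,
                           haldane_corrected=haldane)


def apply_rule(rule: RuleSpec, earliest, delta) -> np.ndarray:
    earliest = np.asarray(earliest, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return (earliest >= rule.theta_base) | (delta > rule.theta_delta)


def derive_delta_rule(earliest, delta, labels):
    """Exhaustive grid search for the two-threshold rule maximizing Youden.

    The grid covers all observed earliest-score values for ``theta_base``
    (plus a sentinel above the maximum, so the rule can ignore the baseline
    term) and all observed delta values for ``theta_delta`` (whose strict
    ">" lets the maximum act as the ignore-delta sentinel).  Ties go to the
    lexicographically smaller ``(theta_base, theta_delta)``.

    Returns ``(RuleSpec, RulePerformance)``.
    """
    labels = _check_labels(labels)
    earliest = np.asarray(earliest, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if len(earliest) != len(delta) or len(earliest) != len(labels):
        raise ValueError("earliest, delta and labels must be aligned")
    base_grid = np.append(np.unique(earliest), np.max(earliest) + 1)
    delta_grid = np.unique(delta)
    if base_grid.size == 0 or delta_grid.size == 0:
        raise ValueError("degenerate grid: no observed score values")
    best = None
    for tb in base_grid:
        base_pos = earliest >= tb
        for td in delta_grid:
            positive = base_pos | (delta > td)
            counts = _confusion(positive, labels)
            sens = counts["TP"] / (counts["TP"] + counts["FN"])
            spec = counts["TN"] / (counts["TN"] + counts["FP"])
            j = sens + spec - 1.0
            if best is None or j > best[2] + 1e-12:
                best = (float(tb), float(td), j)
    rule = RuleSpec(theta_base=best[0], theta_delta=best[1])
    return rule, evaluate_rule(apply_rule(rule, earliest, delta), labels)


def adjusted_or(positive, labels, covariates: pd.DataFrame):
    """Covariate-adjusted odds ratio for a rule indicator via unconditional
    logistic regression (Wald 95% CI).

    Raises on a constant indicator or on (quasi-)separation, recommending a
    penalized fit in the latter case.
    """
    import statsmodels.api as sm

    labels = _check_labels(labels)
    positive = np.asarray(positive).astype(float)
    if positive.min() == positive.max():
        raise ValueError("rule indicator is constant; no adjusted OR estimable")
    X = pd.DataFrame({"rule": positive}, index=covariates.index)
    X = pd.concat([X, covariates.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(labels.astype(float), X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ValueError(
            "logistic fit failed (possible separation); consider a penalized "
            f"fallback: {exc}") from exc
    beta = fit.params["rule"]
    se = fit.bse["rule"]
    if not np.isfinite(se) or se > 50 or abs(beta) > 15:
        raise ValueError("perfect or quasi-separation detected; "
                         "consider a penalized (Firth-style) fallback")
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return float(np.exp(beta)), ci


# --- trajectories ------------------------------------------------------------

def _trajectory_design(df: pd.DataFrame, windows_time_order: list, covariates: list):
    """Fixed-effects design: intercept, window dummies (earliest window is
    the reference), group, group x window, covariates."""
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for w in windows_time_order[1:]:
        X[f"win[{w}]"] = (df["window"] == w).astype(float)
    X["group"] = df["group"].astype(float)
    for w in windows_time_order[1:]:
        X[f"group:win[{w}]"] = X["group"] * X[f"win[{w}]"]
    for c in covariates:
        X[c] = df[c].astype(float)
    return X


def fit_trajectories(df: pd.DataFrame, *, covariates: Optional[list] = None,
                     windows_time_order: Optional[list] = None,
                     select_re: bool = True) -> TrajectoryFit:
    """Linear mixed model of windowed scores over pre-index time.

    ``df`` is long format with columns ``patient_id``, ``window``,
    ``total``, ``group`` (1 = case) and any covariates.  Windows are
    ordered in clock time (farthest from the index first); the earliest
    window is the reference level.  A patient-level random intercept is
    always present; a random slope over window time is added when it lowers
    the AIC (ML fits).  Consecutive-window contrasts are reported per group,
    plus a joint Wald test of the group x window interaction.
    """
    import statsmodels.api as sm

    covariates = covariates or []
    if windows_time_order is None:
        labels_sorted = sorted(df["window"].unique())
        windows_time_order = list(reversed(labels_sorted))  # W4 ... W1
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    X = _trajectory_design(df, windows_time_order, covariates)
    y = df["total"].astype(float)
    groups = df["patient_id"]
    time_num = df["window"].map({w: i for i, w in enumerate(windows_time_order)}).astype(float)

    def _fit(model):
        for method in (None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=False, disp=False, **kwargs)
                if np.isfinite(res.aic):
                    return res
            except (np.linalg.LinAlgError, ValueError):
                continue
        return None

    fits = {}
    fits["intercept"] = _fit(sm.MixedLM(y, X, groups=groups))
    if select_re:
        exog_re = pd.DataFrame({"const": 1.0, "time": time_num})
        fits["intercept+slope"] = _fit(sm.MixedLM(y, X, groups=groups, exog_re=exog_re))
    valid = {k: f for k, f in fits.items() if f is not None}
    if not valid:
        raise RuntimeError("mixed model did not converge under any optimizer; "
                           "check for degenerate window structure")
    re_structure = min(valid, key=lambda k: valid[k].aic)
    fit = valid[re_structure]

    k_fe = X.shape[1]
    fe = fit.fe_params
    cov_fe = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    names = list(X.columns)

    def contrast_vector(group: int, w_from: str, w_to: str) -> np.ndarray:
        L = np.zeros(k_fe)
        for w, s in ((w_to, 1.0), (w_from, -1.0)):
            if w != windows_time_order[0]:
                L[names.index(f"win[{w}]")] += s
                if group == 1:
                    L[names.index(f"group:win[{w}]")] += s
        return L

    rows = []
    for g, gname in ((0, "control"), (1, "case")):
        for w_from, w_to in zip(windows_time_order[:-1], windows_time_order[1:]):
            L = contrast_vector(g, w_from, w_to)
            est = float(L @ fe)
            se = float(np.sqrt(L @ cov_fe @ L))
            z = est / se if se > 0 else 0.0
            rows.append({"group": gname, "interval": f"{w_from}->{w_to}",
                         "estimate": est, "se": se, "z": z,
                         "p": float(2.0 * stats.norm.sf(abs(z)))})
    contrasts = pd.DataFrame(rows)

    inter_idx = [names.index(c) for c in names if c.startswith("group:win")]
    b = np.asarray(fe)[inter_idx]
    C = cov_fe[np.ix_(inter_idx, inter_idx)]
    try:
        wald = float(b @ np.linalg.solve(C, b))
        interaction_p = float(stats.chi2.sf(wald, len(inter_idx)))
    except np.linalg.LinAlgError:
        interaction_p = np.nan

    return TrajectoryFit(
        fixed_effects=fe, aic=float(fit.aic), re_structure=re_structure,
        contrasts=contrasts, interaction_p=interaction_p,
        converged=bool(getattr(fit, "converged", True)),
        diagnostics={"aics": {k: float(f.aic) for k, f in valid.items()},
                     "n_obs": int(len(df))},
    )


# --- baseline table ----------------------------------------------------------

def _is_binary(series: pd.Series) -> bool:
    vals = pd.unique(series.dropna())
    return len(vals) <= 2 and set(np.asarray(vals).astype(float)) <= {0.0, 1.0}


def summarize_baseline(cases: pd.DataFrame, controls: pd.DataFrame,
                       normality_alpha: float = 0.05) -> pd.DataFrame:
    """Baseline characteristics table with group-comparison p-values.

    Binary characteristics are summarized as n (%) with a two-sided Fisher
    exact test; continuous ones as median (IQR) with Student's t when both
    groups pass Shapiro-Wilk normality at ``normality_alpha``, else the
    Wilcoxon rank-sum test.
    """
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in cases.columns:
        if col not in controls.columns:
            continue
        x, y = cases[col].dropna(), controls[col].dropna()
        if _is_binary(cases[col]) and _is_binary(controls[col]):
            a, b = int(x.astype(float).sum()), len(x) - int(x.astype(float).sum())
            c, d = int(y.astype(float).sum()), len(y) - int(y.astype(float).sum())
            _, p = stats.fisher_exact([[a, b], [c, d]])
            rows.append({
                "characteristic": col, "type": "binary",
                "cases": f"{a} ({100.0 * a / len(x):.0f}%)",
                "controls": f"{c} ({100.0 * c / len(y):.0f}%)",
                "cases_pct": 100.0 * a / len(x),
                "controls_pct": 100.0 * c / len(y),
                "test": "fisher", "p": float(p)})
        else:
            xv, yv = x.astype(float), y.astype(float)
            normal = (len(xv) >= 3 and len(yv) >= 3
                      and stats.shapiro(xv).pvalue > normality_alpha
                      and stats.shapiro(yv).pvalue > normality_alpha)
            if normal:
                test, p = "t", stats.ttest_ind(xv, yv).pvalue
            else:
                test, p = "wilcoxon", stats.ranksums(xv, yv).pvalue
            rows.append({
                "characteristic": col, "type": "continuous",
                "cases": f"{xv.median():.0f} ({xv.quantile(.25):.0f}-{xv.quantile(.75):.0f})",
                "controls": f"{yv.median():.0f} ({yv.quantile(.25):.0f}-{yv.quantile(.75):.0f})",
                "cases_pct": np.nan, "controls_pct": np.nan,
                "test": test, "p": float(p)})
    return pd.DataFrame(rows)
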