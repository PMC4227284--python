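"""Discrimination and rule machinery against independent oracles:
brute-force pair counting for the AUC, bootstrap for the paired DeLong test,
exhaustive enumeration for Youden and the two-threshold grid search, and
parameter recovery for the adjusted odds ratio and the mixed model."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wardscore.evaluation import (adhoc_z_unequal, adjusted_or, auc_by_window,
                                  auc_delong, delong_paired_test,
                                  derive_delta_rule, evaluate_rule,
                                  fit_trajectories, summarize_baseline,
                                  youden_threshold, apply_rule, RuleSpec)


def brute_force_auc(scores, labels):
    """Oracle: concordant-pair fraction with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAucDelong:
    def test_perfect_separation(self):
        assert auc_delong([3, 4, 1, 2], [1, 1, 0, 0]).auc == 1.0

    def test_all_ties_give_half(self):
        assert auc_delong([5, 5, 5, 5], [1, 1, 0, 0]).auc == 0.5

    def test_partial_ties_match_hand_count(self):
        # cases {2,3}, controls {1,3}: (2>1) + (2<3 -> 0) + (3>1) + (3=3 -> 1/2) = 2.5/4
        result = auc_delong([2, 3, 1, 3], [1, 1, 0, 0])
        assert result.auc == pytest.approx(0.625)
        assert result.auc == pytest.approx(brute_force_auc([2, 3, 1, 3], [1, 1, 0, 0]))

    def test_brute_force_equivalence_random_datasets(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 12, size=n).astype(float)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auc_delong(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300) + np.repeat([0.0, 0.8], 150)
        labels = np.repeat([0, 1], 150)
        assert auc_delong(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_reversed_labels_complement(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        a = auc_delong(scores, labels).auc
        b = auc_delong(scores, ~labels).auc
        assert a + b == pytest.approx(1.0)

    def test_variance_nonnegative_and_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.normal(size=60)
            labels = rng.random(60) < 0.5
            if labels.all() or not labels.any():
                continue
            r = auc_delong(scores, labels)
            assert r.variance >= 0
            assert r.ci95[0] <= r.auc <= r.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([1, 2, 3], [1, 1, 1])

    def test_ci_coverage_near_nominal_under_null(self):
        """95% CI covers the true AUC of 0.5 in ~95% of null simulations."""
        rng = np.random.default_rng(8)
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            scores = rng.normal(size=100)
            labels = np.repeat([True, False], 50)
            lo, hi = auc_delong(scores, labels).ci95
            covered += lo <= 0.5 <= hi
        assert abs(covered / n_sim - 0.95) < 0.03


class TestDelongPairedTest:
    def test_identical_scores_give_null(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=60)
        labels = np.repeat([True, False], 30)
        z, p = delong_paired_test(s, s, labels)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=60)
        labels = np.repeat([True, False], 30)
        z, p = delong_paired_test(s, np.exp(2 * s) + 7, labels)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [1, 0])

    def test_against_bootstrap_reference(self):
        """Two-sided p agrees with a paired-bootstrap AUC-difference
        reference within 0.05 on a small fixed dataset (B = 10,000)."""
        rng = np.random.default_rng(6)
        n = 60
        labels = np.repeat([True, False], n // 2)
        latent = rng.normal(size=n) + labels * 1.0
        a = latent + rng.normal(scale=0.8, size=n)
        b = latent + rng.normal(scale=1.6, size=n)
        z, p = delong_paired_test(a, b, labels)

        B = 10_000
        idx_pos = np.where(labels)[0]
        idx_neg = np.where(~labels)[0]
        diffs = np.empty(B)
        for i in range(B):
            bp = rng.choice(idx_pos, size=len(idx_pos), replace=True)
            bn = rng.choice(idx_neg, size=len(idx_neg), replace=True)
            take = np.concatenate([bp, bn])
            lab = np.concatenate([np.ones(len(bp), bool), np.zeros(len(bn), bool)])
            diffs[i] = auc_delong(a[take], lab).auc - auc_delong(b[take], lab).auc
        observed = auc_delong(a, labels).auc - auc_delong(b, labels).auc
        # symmetric bootstrap p for H0: no AUC difference
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert abs(p - p_boot) < 0.05


class TestAdhocZ:
    def test_equal_aucs_give_zero(self):
        z, p = adhoc_z_unequal(0.75, 4e-4, 0.75, 9e-4)
        assert z == 0.0 and p == 1.0

    def test_equal_variance_identity(self):
        # var_a = var_b = v and rho = 0.5 collapse the denominator to sqrt(v)
        v = 6.25e-4
        z, _ = adhoc_z_unequal(0.80, v, 0.75, v)
        assert z == pytest.approx(0.05 / np.sqrt(v))

    def test_plug_in_arithmetic(self):
        z, p = adhoc_z_unequal(0.78, 4e-4, 0.76, 4e-4)
        assert z == pytest.approx(1.0)
        assert p == pytest.approx(2 * stats.norm.sf(1.0))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            adhoc_z_unequal(0.7, 0.0, 0.6, 1e-4)


class TestYoudenThreshold:
    def brute_force(self, scores, labels):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        best = None
        for t in np.unique(scores):
            pos = scores >= t
            sens = (pos & labels).sum() / labels.sum()
            spec = (~pos & ~labels).sum() / (~labels).sum()
            j = sens + spec - 1
            if best is None or j > best[1] + 1e-12:
                best = (t, j)
        return best

    def test_separable_data(self):
        t, perf = youden_threshold([5, 6, 1, 2], [1, 1, 0, 0])
        assert t == 5 and perf.youden == pytest.approx(1.0)

    def test_identical_distributions_give_zero_j(self):
        t, perf = youden_threshold([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert perf.youden == pytest.approx(0.0)

    def test_matches_exhaustive_scan_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(8, 80))
            scores = rng.integers(0, 15, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            t, perf = youden_threshold(scores, labels)
            t_b, j_b = self.brute_force(scores, labels)
            assert perf.youden == pytest.approx(j_b)
            assert t == t_b


class TestDeltaRule:
    def brute_force(self, earliest, delta, labels):
        earliest = np.asarray(earliest, float)
        delta = np.asarray(delta, float)
        labels = np.asarray(labels, bool)
        best = None
        for tb in np.append(np.unique(earliest), earliest.max() + 1):
            for td in np.unique(delta):
                pos = (earliest >= tb) | (delta > td)
                sens = (pos & labels).sum() / labels.sum()
                spec = (~pos & ~labels).sum() / (~labels).sum()
                j = sens + spec - 1
                if best is None or j > best[2] + 1e-12:
                    best = (tb, td, j)
        return best

    def test_separable_on_delta(self):
        earliest = [2, 1, 2, 1]
        delta = [1, 2, 0, -1]
        labels = [1, 1, 0, 0]
        rule, perf = derive_delta_rule(earliest, delta, labels)
        assert perf.youden == pytest.approx(1.0)
        assert rule.theta_delta == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            earliest = rng.integers(0, 8, size=n).astype(float)
            delta = rng.integers(-4, 6, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            rule, perf = derive_delta_rule(earliest, delta, labels)
            tb, td, j = self.brute_force(earliest, delta, labels)
            assert perf.youden == pytest.approx(j)
            assert (rule.theta_base, rule.theta_delta) == (tb, td)

    def test_grid_superset_never_worse_than_single_threshold(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            earliest = rng.integers(0, 10, size=50).astype(float)
            delta = rng.integers(-3, 5, size=50).astype(float)
            labels = rng.random(50) < 0.5
            if labels.all() or not labels.any():
                continue
            _, perf_rule = derive_delta_rule(earliest, delta, labels)
            _, perf_single = youden_threshold(earliest, labels)
            assert perf_rule.youden >= perf_single.youden - 1e-12


class TestEvaluateRule:
    def test_constructed_2x2_arithmetic(self):
        # TP=246, FN=82, FP=92, TN=236
        positive = np.array([True] * 246 + [False] * 82 + [True] * 92 + [False] * 236)
        labels = np.array([True] * 328 + [False] * 328)
        perf = evaluate_rule(positive, labels)
        assert perf.sensitivity == pytest.approx(0.750, abs=5e-4)
        assert perf.specificity == pytest.approx(0.720, abs=5e-3)
        assert perf.or_crude == pytest.approx(7.70, abs=0.01)
        assert not perf.haldane_corrected

    def test_all_positive_rule(self):
        perf = evaluate_rule([1, 1, 1, 1], [1, 1, 0, 0])
        assert perf.sensitivity == 1.0 and perf.specificity == 0.0
        assert perf.haldane_corrected

    def test_symmetric_table_or_is_square_of_ratio(self):
        # TP=TN=30, FP=FN=10 -> OR = (30/10)^2 = 9
        positive = np.array([True] * 30 + [False] * 10 + [True] * 10 + [False] * 30)
        labels = np.array([True] * 40 + [False] * 40)
        perf = evaluate_rule(positive, labels)
        assert perf.or_crude == pytest.approx((30 / 10) ** 2)

    def test_balanced_design_or_sens_spec_identity(self):
        """In a balanced 1:1 design, OR = (sens*spec)/((1-sens)(1-spec))."""
        rng = np.random.default_rng(11)
        labels = np.repeat([True, False], 200)
        positive = np.where(labels, rng.random(400) < 0.7, rng.random(400) < 0.25)
        perf = evaluate_rule(positive, labels)
        s, p = perf.sensitivity, perf.specificity
        assert perf.or_crude == pytest.approx((s * p) / ((1 - s) * (1 - p)))


class TestAdjustedOr:
    def test_independent_covariates_leave_or_near_crude(self):
        rng = np.random.default_rng(12)
        n = 2000
        positive = rng.random(n) < 0.4
        logit = -1.0 + 1.2 * positive
        labels = rng.random(n) < 1 / (1 + np.exp(-logit))
        cov = pd.DataFrame({"age": rng.normal(60, 10, n), "female": rng.random(n) < 0.5})
        crude = evaluate_rule(positive, labels).or_crude
        or_adj, ci = adjusted_or(positive, labels, cov)
        assert ci[0] <= crude <= ci[1]

    def test_known_logit_recovered_within_2_se(self):
        rng = np.random.default_rng(13)
        n = 3000
        beta = 1.5
        positive = rng.random(n) < 0.35
        age = rng.normal(0, 1, n)
        logit = -0.8 + beta * positive + 0.5 * age
        labels = rng.random(n) < 1 / (1 + np.exp(-logit))
        or_adj, ci = adjusted_or(positive, labels, pd.DataFrame({"age": age}))
        log_or, log_lo = np.log(or_adj), np.log(ci[0])
        se = (log_or - log_lo) / 1.96
        assert abs(log_or - beta) < 2 * se

    def test_constant_indicator_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adjusted_or([1, 1, 1, 1], [1, 0, 1, 0], pd.DataFrame(index=range(4)))

    def test_separation_flagged(self):
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        positive = labels.copy()
        with pytest.raises(ValueError, match="separation|penalized"):
            adjusted_or(positive, labels, pd.DataFrame(index=range(6)))


def _trajectory_frame(rng, n_per_arm=150, case_slope=0.8, sigma=1.0):
    rows = []
    for g in (0, 1):
        for i in range(n_per_arm):
            pid = f"g{g}p{i}"
            intercept = rng.normal(2.0 + 0.5 * g, 1.0)
            for t, w in enumerate(["W4", "W3", "W2", "W1"]):
                mu = intercept + (case_slope * t if g == 1 else 0.0)
                rows.append({"patient_id": pid, "window": w, "group": g,
                             "total": rng.normal(mu, sigma),
                             "age": rng.normal(60, 10)})
    return pd.DataFrame(rows)


class TestTrajectories:
    def test_rising_cases_detected(self):
        rng = np.random.default_rng(14)
        df = _trajectory_frame(rng, n_per_arm=300, case_slope=0.6)
        fit = fit_trajectories(df, covariates=["age"])
        assert fit.interaction_p < 0.05
        case_rises = fit.contrasts.query("group == 'case'")["estimate"]
        assert (case_rises > 0).all()

    def test_duplicating_rows_leaves_point_estimates_unchanged(self):
        rng = np.random.default_rng(15)
        df = _trajectory_frame(rng, n_per_arm=60, case_slope=0.5)
        fit1 = fit_trajectories(df, covariates=["age"], select_re=False)
        dup = pd.concat([df, df.assign(patient_id=df["patient_id"] + "_dup")],
                        ignore_index=True)
        fit2 = fit_trajectories(dup, covariates=["age"], select_re=False)
        assert np.allclose(fit1.fixed_effects, fit2.fixed_effects, atol=1e-5)

    def test_contrast_count_is_groups_times_intervals(self):
        rng = np.random.default_rng(16)
        fit = fit_trajectories(_trajectory_frame(rng, n_per_arm=40), covariates=["age"],
                               select_re=False)
        assert len(fit.contrasts) == 2 * 3

    def test_single_group_rejected(self):
        rng = np.random.default_rng(17)
        df = _trajectory_frame(rng, n_per_arm=20)
        with pytest.raises(ValueError):
            fit_trajectories(df[df["group"] == 1], covariates=["age"])


class TestAucByWindow:
    def test_flipped_labels_complement_table(self, small_cohort):
        from wardscore.pipeline import match_cohort, score_pairs
        _, _, pairs, _ = match_cohort(small_cohort, seed=1)
        scores_df = score_pairs(small_cohort, pairs[:25])
        labels = {pid: role == "case" for pid, role in
                  scores_df[["patient_id", "role"]].drop_duplicates().itertuples(index=False)}
        table = auc_by_window(scores_df, labels)
        flipped = auc_by_window(scores_df, {k: not v for k, v in labels.items()})
        merged = table.merge(flipped, on=["score", "window"], suffixes=("", "_flip"))
        valid = merged.dropna(subset=["auc", "auc_flip"])
        assert len(valid) > 0
        assert np.allclose(valid["auc"] + valid["auc_flip"], 1.0)

    def test_single_class_window_flagged_not_dropped(self):
        df = pd.DataFrame({
            "patient_id": ["a", "b"], "window": ["W1", "W1"],
            "score": ["SOFA", "SOFA"], "total": [3, 1],
            "in_hospital": [True, True]})
        table = auc_by_window(df, {"a": True, "b": True})
        assert len(table) == 1
        assert np.isnan(table.iloc[0]["auc"]) and table.iloc[0]["note"] != ""


class TestSummarizeBaseline:
    def test_printed_style_percentages(self):
        cases = pd.DataFrame({"severe_sepsis": [1] * 248 + [0] * 80})
        controls = pd.DataFrame({"severe_sepsis": [1] * 106 + [0] * 222})
        table = summarize_baseline(cases, controls)
        row = table.iloc[0]
        assert row["cases_pct"] == pytest.approx(75.6, abs=0.05)
        assert row["controls_pct"] == pytest.approx(32.3, abs=0.05)
        assert row["p"] < 0.001

    def test_identical_2x2_gives_fisher_p_one(self):
        g = pd.DataFrame({"flag": [1] * 10 + [0] * 10})
        table = summarize_baseline(g, g.copy())
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_continuous_summary_uses_median_iqr(self):
        rng = np.random.default_rng(18)
        cases = pd.DataFrame({"age": rng.normal(67, 15, 300)})
        controls = pd.DataFrame({"age": rng.normal(64, 15, 300)})
        table = summarize_baseline(cases, controls)
        assert table.iloc[0]["type"] == "continuous"
        assert table.iloc[0]["test"] in ("t", "wilcoxon")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_baseline(pd.DataFrame({"x": []}), pd.DataFrame({"x": [1]}))
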