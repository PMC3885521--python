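import numpy as np
import pytest
from scipy import stats

from pai import (
    EvaluationError,
    PatientPrediction,
    SchemaError,
    baseline_balance,
    se_prediction,
    split_by_threshold,
    true_error,
)
from pai.evaluation import (
    build_report,
    cohens_d_ci,
    compare_groups,
    compare_optimal_nonoptimal,
    evaluate_predictions,
    report_to_json,
    sd_of_errors,
)


def make_prediction(pid, pred_a, pred_b, arm="A", observed=None, arms=("A", "B")):
    pai = abs(pred_a - pred_b)
    if pred_a == pred_b:
        optimal = "none"
    else:
        optimal = arms[0] if pred_a < pred_b else arms[1]
    received = (
        "indeterminate" if optimal == "none"
        else ("true" if arm == optimal else "false")
    )
    return PatientPrediction(
        patient_id=pid,
        pred_by_arm={arms[0]: pred_a, arms[1]: pred_b},
        factual_arm=arm,
        pai=pai,
        optimal_arm=optimal,
        received_optimal=received,
        observed_endpoint=observed,
    )


class TestErrorMetrics:
    def test_true_error_hand_arithmetic(self):
        assert true_error([10, 20], [12, 16]) == pytest.approx(3.0)

    def test_true_error_zero_on_perfect_prediction(self):
        v = [3.0, 7.5, 12.0]
        assert true_error(v, v) == 0.0

    def test_se_prediction_hand_arithmetic(self):
        # errors exactly [3, 4] -> sqrt((9+16)/2)
        assert se_prediction([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))

    def test_se_prediction_zero_errors(self):
        assert se_prediction([5.0, 5.0], [5.0, 5.0]) == 0.0

    def test_metrics_match_independent_oracles(self):
        rng = np.random.default_rng(3)
        obs, pred = rng.uniform(0, 30, 50), rng.uniform(0, 30, 50)
        err = obs - pred
        assert true_error(obs, pred) == pytest.approx(np.abs(err).mean())
        assert se_prediction(obs, pred) == pytest.approx(
            np.sqrt((err**2).mean())
        )
        assert sd_of_errors(obs, pred) == pytest.approx(np.std(err, ddof=1))

    def test_true_error_never_exceeds_rmse(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            obs = rng.uniform(0, 30, 25)
            pred = rng.uniform(0, 30, 25)
            assert true_error(obs, pred) <= se_prediction(obs, pred) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            true_error([1.0], [1.0, 2.0])


class TestSplitByThreshold:
    def test_boundary_inclusive_at_threshold(self):
        preds = [
            make_prediction(f"p{i}", a, b)
            for i, (a, b) in enumerate([(10, 11), (10, 12.9), (10, 13), (10, 15)])
        ]
        sig, rest = split_by_threshold(preds, 3.0)
        assert len(sig) == 2 and len(rest) == 2
        assert {p.pai for p in sig} == {3.0, 5.0}

    def test_zero_threshold_keeps_all_determinate(self):
        preds = [
            make_prediction("p1", 10, 12),
            make_prediction("p2", 10, 10),  # tie -> indeterminate
        ]
        sig, rest = split_by_threshold(preds, 0.0)
        assert [p.patient_id for p in sig] == ["p1"]
        assert [p.patient_id for p in rest] == ["p2"]

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(4)
        preds = [
            make_prediction(f"p{i}", float(a), float(b))
            for i, (a, b) in enumerate(rng.uniform(0, 25, size=(40, 2)))
        ]
        sig, rest = split_by_threshold(preds, 3.0)
        assert len(sig) + len(rest) == len(preds)
        assert {p.patient_id for p in sig}.isdisjoint({p.patient_id for p in rest})


class TestCohensD:
    @pytest.mark.parametrize(
        "mean_diff, pooled_sd, expected",
        [(3.58, 6.12, 0.58), (1.78, 6.38, 0.28)],
    )
    def test_d_from_mean_diff_and_pooled_sd(self, mean_diff, pooled_sd, expected):
        assert round(mean_diff / pooled_sd, 2) == expected

    def test_identical_groups_give_null_result(self):
        g = [4.0, 8.0, 12.0, 16.0]
        r = compare_groups(g, list(g))
        assert r.mean_diff == 0.0
        assert r.cohens_d == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_t_and_p_match_scipy(self):
        rng = np.random.default_rng(8)
        opt, non = rng.normal(9, 5, 40), rng.normal(12, 5, 35)
        r = compare_groups(opt, non)
        t_ref = stats.ttest_ind(non, opt, equal_var=True)
        assert r.t_stat == pytest.approx(t_ref.statistic)
        assert r.p_value == pytest.approx(t_ref.pvalue)
        assert r.df == 73
        assert r.cohens_d == pytest.approx(r.mean_diff / r.pooled_sd)

    def test_d_sign_flips_under_group_swap_p_invariant(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(9, 5, 30), rng.normal(12, 5, 28)
        r1, r2 = compare_groups(a, b), compare_groups(b, a)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_noncentral_t_ci_brackets_d_and_inverts_cdf(self):
        lo, hi = cohens_d_ci(2.84, 46, 46)
        d = 2.84 * np.sqrt(2 / 46)
        assert lo < d < hi
        # inverting back: observed t is the right tail quantile at each bound
        df, scale = 90, np.sqrt(2 / 46)
        assert stats.nct.cdf(2.84, df, lo / scale) == pytest.approx(0.975, abs=1e-6)
        assert stats.nct.cdf(2.84, df, hi / scale) == pytest.approx(0.025, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(EvaluationError, match="empty"):
            compare_groups([], [1.0, 2.0])

    def test_compare_excludes_indeterminate(self):
        preds = [
            make_prediction("p1", 10, 14, arm="A", observed=8.0),
            make_prediction("p2", 10, 14, arm="B", observed=15.0),
            make_prediction("p3", 9, 9, arm="A", observed=11.0),  # tie
            make_prediction("p4", 12, 10, arm="B", observed=7.0),
            make_prediction("p5", 12, 10, arm="A", observed=14.0),
        ]
        r = compare_optimal_nonoptimal(preds)
        assert r.n_optimal == 2 and r.n_nonoptimal == 2
        assert r.df == 2


class TestBaselineBalance:
    def test_identical_arms_balanced(self, small_trial):
        # duplicate each patient into both arms -> perfectly balanced
        from dataclasses import replace
        from pai import TrialDataset

        records = []
        for i, r in enumerate(small_trial.records):
            records.append(replace(r, patient_id=f"a{i}", arm=small_trial.arms[0]))
            records.append(replace(r, patient_id=f"b{i}", arm=small_trial.arms[1]))
        ds = TrialDataset(
            records=records,
            arms=small_trial.arms,
            specs=small_trial.specs,
            outcome_transform=small_trial.outcome_transform,
        )
        for res in baseline_balance(ds):
            assert res.p_value == pytest.approx(1.0)

    def test_chi_square_matches_textbook_formula(self):
        # arm A: 30 positive / 10 negative; arm B: 10 / 30 -> chi2 = 20
        from pai import PatientRecord, TrialDataset, VariableSpec

        spec = VariableSpec(
            "flag", "prescriptive", "binary",
            binary_positive_label="yes", binary_negative_label="no",
        )
        records = []
        for arm, n_yes, n_no in (("A", 30, 10), ("B", 10, 30)):
            for i in range(n_yes + n_no):
                records.append(
                    PatientRecord(
                        f"{arm}{i}", arm,
                        {"flag": "yes" if i < n_yes else "no"}, 1.0,
                    )
                )
        ds = TrialDataset(records, arms=("A", "B"), specs=[spec])
        (res,) = baseline_balance(ds)
        table = np.array([[30, 10], [10, 30]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(chi2_hand)

    def test_randomized_trial_shows_no_extreme_imbalance(self):
        from dataclasses import replace as dc_replace

        from pai import SyntheticConfig, generate_trial

        cfg = dc_replace(SyntheticConfig(), n_per_arm=(2500, 2500))
        ds = generate_trial(cfg, seed=77)
        for res in baseline_balance(ds):
            assert res.test in ("t", "chi2")
            assert res.p_value >= 0.001


class TestEvaluateAndReport:
    def _preds(self, n=30, seed=2):
        rng = np.random.default_rng(seed)
        preds = []
        for i in range(n):
            a, b = rng.uniform(2, 20, 2)
            preds.append(
                make_prediction(
                    f"p{i}", a, b,
                    arm=("A" if rng.random() < 0.5 else "B"),
                    observed=float(rng.uniform(0, 25)),
                )
            )
        return preds

    def test_summary_fields_consistent(self):
        preds = self._preds()
        ev = evaluate_predictions(preds, threshold=3.0)
        assert ev.n == len(preds)
        assert ev.n_above_threshold + ev.n_below_threshold == ev.n
        assert ev.true_error <= ev.se_prediction
        assert ev.full_sample.df == (
            ev.full_sample.n_optimal + ev.full_sample.n_nonoptimal - 2
        )

    def test_report_bin_counts_sum_to_n(self):
        preds = self._preds(n=40, seed=6)
        ev = evaluate_predictions(preds)
        report = build_report(preds, ev)
        assert sum(report["histograms"]["pai"]["counts"]) == len(preds)
        n_det = sum(1 for p in preds if p.optimal_arm != "none")
        assert sum(report["histograms"]["predicted_optimal"]["counts"]) == n_det

    def test_report_serialization_deterministic(self):
        preds = self._preds(n=20, seed=9)
        ev = evaluate_predictions(preds)
        a = report_to_json(build_report(preds, ev))
        b = report_to_json(build_report(preds, ev))
        assert a == b

    def test_empty_prediction_list_rejected(self):
        with pytest.raises(SchemaError):
            evaluate_predictions([])
        with pytest.raises(SchemaError):
            build_report([], None)

    def test_all_tie_predictions_cannot_be_evaluated(self):
        preds = [
            make_prediction(f"p{i}", 8.0, 8.0, observed=10.0) for i in range(6)
        ]
        with pytest.raises(EvaluationError):
            evaluate_predictions(preds)
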