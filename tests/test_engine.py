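from dataclasses import replace

import numpy as np
import pytest

from pai import (
    DesignRow,
    PAIError,
    RankDeficiencyError,
    SyntheticConfig,
    TrialDataset,
    build_design_row,
    compute_pai,
    fit_linear_model,
    generate_trial,
    loo_predict,
)
from pai.engine import fit_full_sample, term_names
from pai.synthetic import true_counterfactual_difference
from pai.worked_example import (
    EXAMPLE_PATIENT,
    REFERENCE_CENTERS,
    example_dataset,
)

from _oracle import loo_predict_oracle


class TestBuildDesignRow:
    """The coded design for the bundled example patient, both arms."""

    def setup_method(self):
        self.ds = example_dataset()

    def test_cbt_row_treatment_and_interaction_entries(self):
        row = build_design_row(EXAMPLE_PATIENT, self.ds, "CBT", REFERENCE_CENTERS)
        d = row.as_dict()
        assert d["treatment"] == 0.5
        assert d["treatment:married"] == pytest.approx(-0.25)  # 0.5 * -0.5
        assert d["treatment:prior_adm_trials"] == pytest.approx(0.64)  # 0.5 * 1.28
        assert d["intercept"] == 1.0

    def test_other_arm_negates_every_treatment_entry(self):
        cbt = build_design_row(EXAMPLE_PATIENT, self.ds, "CBT", REFERENCE_CENTERS)
        adm = build_design_row(EXAMPLE_PATIENT, self.ds, "ADM", REFERENCE_CENTERS)
        for term, c_val in cbt.as_dict().items():
            m_val = adm.as_dict()[term]
            if term == "treatment" or term.startswith("treatment:"):
                assert m_val == pytest.approx(-c_val)
            else:
                assert m_val == c_val
        assert adm.as_dict()["treatment:married"] == pytest.approx(0.25)

    def test_interaction_is_product_of_code_and_main(self):
        row = build_design_row(EXAMPLE_PATIENT, self.ds, "CBT", REFERENCE_CENTERS)
        d = row.as_dict()
        for term in row.term_names:
            if term.startswith("treatment:"):
                main = term.split(":", 1)[1]
                assert d[term] == pytest.approx(d["treatment"] * d[main])

    def test_term_order(self):
        names = term_names(self.ds)
        assert names[0] == "intercept"
        tx_idx = names.index("treatment")
        assert all(n.startswith("treatment:") for n in names[tx_idx + 1:])
        assert not any(n.startswith("treatment") for n in names[1:tx_idx])


class TestFitLinearModel:
    def test_exact_linear_data_recovered(self):
        xs = np.arange(10.0)
        rows = [DesignRow(("intercept", "x"), (1.0, x)) for x in xs]
        z = 2.0 + 0.5 * xs
        fit = fit_linear_model(rows, z)
        assert fit.coefficients["intercept"] == pytest.approx(2.0)
        assert fit.coefficients["x"] == pytest.approx(0.5)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_column_raises_rank_error(self):
        rng = np.random.default_rng(5)
        xs = rng.normal(size=12)
        rows = [DesignRow(("intercept", "x", "x_copy"), (1.0, x, x)) for x in xs]
        with pytest.raises(RankDeficiencyError):
            fit_linear_model(rows, rng.normal(size=12))

    def test_too_few_observations_raises(self):
        rows = [DesignRow(("intercept", "x"), (1.0, float(i))) for i in range(2)]
        with pytest.raises(PAIError, match="n=2"):
            fit_linear_model(rows, [1.0, 2.0])


class TestComputePAI:
    def test_worked_example_predictions(self):
        pai, optimal = compute_pai({"CBT": 13.0, "ADM": 18.6})
        assert pai == pytest.approx(5.6)
        assert optimal == "CBT"

    def test_exact_tie_gives_none(self):
        pai, optimal = compute_pai({"A": 7.4, "B": 7.4})
        assert pai == 0.0
        assert optimal == "none"

    def test_symmetry_under_arm_swap(self):
        pai, optimal = compute_pai({"A": 18.6, "B": 13.0})
        assert pai == pytest.approx(5.6)
        assert optimal == "B"

    def test_higher_is_better_flips_choice(self):
        pai, optimal = compute_pai({"A": 10.0, "B": 4.0}, better_direction="higher")
        assert optimal == "A"

    def test_non_finite_prediction_rejected(self):
        with pytest.raises(PAIError):
            compute_pai({"A": float("nan"), "B": 3.0})


class TestLooPredict:
    def test_matches_bruteforce_oracle(self, small_trial):
        preds = loo_predict(small_trial)
        oracle = loo_predict_oracle(small_trial)
        for mine, ref in zip(preds, oracle):
            for arm in small_trial.arms:
                assert mine.pred_by_arm[arm] == pytest.approx(
                    ref["pred_by_arm"][arm], abs=1e-8
                )
            assert mine.pai == pytest.approx(ref["pai"], abs=1e-8)
            assert mine.optimal_arm == ref["optimal_arm"]

    def test_matches_oracle_per_fold_centering(self, small_trial):
        preds = loo_predict(small_trial, centering="per_fold")
        oracle = loo_predict_oracle(small_trial, centering="per_fold")
        for mine, ref in zip(preds, oracle):
            for arm in small_trial.arms:
                assert mine.pred_by_arm[arm] == pytest.approx(
                    ref["pred_by_arm"][arm], abs=1e-8
                )

    def test_zero_noise_factual_predictions_exact(self, noiseless_trial):
        dataset, cfg = noiseless_trial
        preds = loo_predict(dataset)
        for p in preds:
            assert p.factual_prediction == pytest.approx(
                p.observed_endpoint, abs=1e-6
            )

    def test_zero_noise_pai_equals_true_counterfactual_difference(
        self, noiseless_trial
    ):
        dataset, cfg = noiseless_trial
        preds = loo_predict(dataset)
        truth = true_counterfactual_difference(cfg, dataset)
        for p, t in zip(preds, truth):
            assert p.pai == pytest.approx(t, abs=1e-6)

    def test_predictions_nonnegative_and_pai_consistent(self, small_trial):
        for p in loo_predict(small_trial):
            assert all(v >= 0 for v in p.pred_by_arm.values())
            a, b = (p.pred_by_arm[arm] for arm in small_trial.arms)
            assert p.pai == pytest.approx(abs(a - b))
            assert p.pai >= 0

    def test_centering_invariance(self, small_trial):
        base = loo_predict(small_trial)
        shifted_specs = [
            replace(s, centering_constant=5.0)
            if s.kind in ("continuous", "capped_count")
            else s
            for s in small_trial.specs
        ]
        shifted = TrialDataset(
            records=small_trial.records,
            arms=small_trial.arms,
            specs=shifted_specs,
            outcome_transform=small_trial.outcome_transform,
        )
        for p, q in zip(base, loo_predict(shifted)):
            for arm in small_trial.arms:
                assert p.pred_by_arm[arm] == pytest.approx(
                    q.pred_by_arm[arm], abs=1e-8
                )
            assert p.pai == pytest.approx(q.pai, abs=1e-8)

    def test_arm_code_swap_leaves_predictions_unchanged(self, small_trial):
        base = loo_predict(small_trial)
        swapped_ds = TrialDataset(
            records=small_trial.records,
            arms=(small_trial.arms[1], small_trial.arms[0]),
            specs=small_trial.specs,
            outcome_transform=small_trial.outcome_transform,
        )
        swapped = loo_predict(swapped_ds)
        for p, q in zip(base, swapped):
            for arm in small_trial.arms:
                assert p.pred_by_arm[arm] == pytest.approx(
                    q.pred_by_arm[arm], abs=1e-8
                )
            assert p.optimal_arm == q.optimal_arm

    def test_arm_code_swap_flips_treatment_coefficients(self, small_trial):
        fit_a = fit_full_sample(small_trial)
        swapped_ds = TrialDataset(
            records=small_trial.records,
            arms=(small_trial.arms[1], small_trial.arms[0]),
            specs=small_trial.specs,
            outcome_transform=small_trial.outcome_transform,
        )
        fit_b = fit_full_sample(swapped_ds)
        for term, beta in fit_a.coefficients.items():
            if term == "treatment" or term.startswith("treatment:"):
                assert fit_b.coefficients[term] == pytest.approx(-beta, abs=1e-8)
            else:
                assert fit_b.coefficients[term] == pytest.approx(beta, abs=1e-8)

    def test_loo_model_never_sees_held_out_patient(self, small_trial):
        # corrupting patient i's outcome must not change patient i's predictions
        preds = loo_predict(small_trial)
        records = list(small_trial.records)
        corrupted = replace(records[0], observed_endpoint=400.0)
        ds2 = TrialDataset(
            records=[corrupted] + records[1:],
            arms=small_trial.arms,
            specs=small_trial.specs,
            outcome_transform=small_trial.outcome_transform,
        )
        preds2 = loo_predict(ds2)
        for arm in small_trial.arms:
            assert preds2[0].pred_by_arm[arm] == pytest.approx(
                preds[0].pred_by_arm[arm], abs=1e-10
            )
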