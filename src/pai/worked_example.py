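"""A fully worked single-patient example of the PAI arithmetic.

The package bundles a reference coefficient set (from a leave-one-out fit
of the nine-variable depression model, on the square-root HRSD scale) and
one example patient, so the entire prediction chain -- coding, design row,
linear predictor under each arm, back-transform, PAI -- can be traced by
hand.  The example patient is moderately depressed at intake (HRSD 20),
56 years old, of high intellectual level, chronically depressed, unmarried,
unemployed, reports 3 life stressors, has no comorbid personality disorder
and two prior medication trials.

The centering constants are fixed at the values under which the reference
coefficients were estimated (e.g. intake HRSD centered at 23.75, age at
40.33, life stressors at 3.65, capped prior trials at 0.72); reusing them
verbatim is what makes the coefficient table portable to a new patient.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import ModelFit, PatientPrediction, PatientRecord, TrialDataset, VariableSpec
from .engine import build_design_row, compute_pai
from .preprocessing import back_transform

ARMS = ("CBT", "ADM")

#: Reference coefficients on the square-root HRSD scale.
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "intercept": 3.15,
    "intake_hrsd": 0.05,
    "age": 0.01,
    "iq_band": -0.18,
    "chronic": 0.39,
    "married": -0.45,
    "employed": -0.50,
    "life_stressors": -0.07,
    "personality_disorder": 0.17,
    "prior_adm_trials": 0.28,
    "treatment": -0.42,
    "treatment:married": -1.10,
    "treatment:employed": 1.03,
    "treatment:life_stressors": -0.35,
    "treatment:personality_disorder": 0.66,
    "treatment:prior_adm_trials": -0.17,
}

#: Fixed centering constants matching the reference coefficient set.
REFERENCE_CENTERS: dict[str, float] = {
    "intake_hrsd": 23.75,
    "age": 40.33,
    "life_stressors": 3.65,
    "prior_adm_trials": 0.72,
}

EXAMPLE_SPECS: tuple[VariableSpec, ...] = (
    VariableSpec("intake_hrsd", "prognostic", "continuous",
                 centering_constant=REFERENCE_CENTERS["intake_hrsd"]),
    VariableSpec("age", "prognostic", "continuous",
                 centering_constant=REFERENCE_CENTERS["age"]),
    VariableSpec("iq_band", "prognostic", "ordinal3"),
    VariableSpec("chronic", "prognostic", "binary",
                 binary_positive_label="chronic",
                 binary_negative_label="nonchronic"),
    VariableSpec("married", "prescriptive", "binary",
                 binary_positive_label="married",
                 binary_negative_label="unmarried"),
    VariableSpec("employed", "prescriptive", "binary",
                 binary_positive_label="employed",
                 binary_negative_label="unemployed"),
    VariableSpec("life_stressors", "prescriptive", "continuous",
                 centering_constant=REFERENCE_CENTERS["life_stressors"]),
    VariableSpec("personality_disorder", "prescriptive", "binary",
                 binary_positive_label="pd",
                 binary_negative_label="no_pd"),
    VariableSpec("prior_adm_trials", "prescriptive", "capped_count", cap=2,
                 centering_constant=REFERENCE_CENTERS["prior_adm_trials"]),
)

EXAMPLE_PATIENT = PatientRecord(
    patient_id="EX001",
    arm="CBT",
    covariates={
        "intake_hrsd": 20,
        "age": 56,
        "iq_band": "high",
        "chronic": "chronic",
        "married": "unmarried",
        "employed": "unemployed",
        "life_stressors": 3,
        "personality_disorder": "no_pd",
        "prior_adm_trials": 2,
    },
    observed_endpoint=None,
)


@dataclass(frozen=True)
class WorkedExample:
    """Result of running the example patient through the reference model."""

    prediction: PatientPrediction
    linear_predictor: dict[str, float]  # per arm, sqrt scale
    contributions: dict[str, dict[str, float]]  # per arm: term -> value*beta

    @property
    def pred_cbt(self) -> float:
        return self.prediction.pred_by_arm["CBT"]

    @property
    def pred_adm(self) -> float:
        return self.prediction.pred_by_arm["ADM"]

    @property
    def pai(self) -> float:
        return self.prediction.pai


def example_dataset() -> TrialDataset:
    """A one-patient predict-only dataset holding the example patient."""
    return TrialDataset(
        records=[EXAMPLE_PATIENT],
        arms=ARMS,
        specs=EXAMPLE_SPECS,
        outcome_transform="sqrt",
    )


def run_worked_example() -> WorkedExample:
    """Predict the example patient's endpoint under both arms.

    Runs the regular engine path: code the covariates, build the design row
    under each arm (the second arm's row is the first with the treatment
    code sign-flipped in the treatment and interaction entries), take the
    inner product with the reference coefficients, square the result, and
    difference the two predictions to get the PAI.
    """
    dataset = example_dataset()
    fit = ModelFit(
        coefficients=REFERENCE_COEFFICIENTS,
        n_fit=153,
        residual_sd=float("nan"),
    )
    linear, contribs, pred_by_arm = {}, {}, {}
    for arm in dataset.arms:
        row = build_design_row(EXAMPLE_PATIENT, dataset, arm, REFERENCE_CENTERS)
        z = fit.predict_row(row)
        linear[arm] = z
        contribs[arm] = {
            t: v * REFERENCE_COEFFICIENTS[t]
            for t, v in zip(row.term_names, row.values)
        }
        pred_by_arm[arm] = back_transform(z, dataset.outcome_transform)
    pai, optimal = compute_pai(pred_by_arm, dataset.better_direction)
    prediction = PatientPrediction(
        patient_id=EXAMPLE_PATIENT.patient_id,
        pred_by_arm=pred_by_arm,
        factual_arm=EXAMPLE_PATIENT.arm,
        pai=pai,
        optimal_arm=optimal,
        received_optimal="indeterminate" if optimal == "none"
        else ("true" if EXAMPLE_PATIENT.arm == optimal else "false"),
        observed_endpoint=None,
    )
    return WorkedExample(
        prediction=prediction, linear_predictor=linear, contributions=contribs
    )


def format_worked_example(example: WorkedExample) -> str:
    """Human-readable trace of the example computation."""
    lines = ["Worked example: single-patient PAI computation", ""]
    lines.append(f"{'term':<34}{'CBT':>10}{'ADM':>10}")
    for term in REFERENCE_COEFFICIENTS:
        c = example.contributions["CBT"][term]
        m = example.contributions["ADM"][term]
        lines.append(f"{term:<34}{c:>10.3f}{m:>10.3f}")
    lines.append(
        f"{'linear predictor (sqrt scale)':<34}"
        f"{example.linear_predictor['CBT']:>10.3f}"
        f"{example.linear_predictor['ADM']:>10.3f}"
    )
    lines.append(
        f"{'predicted endpoint (HRSD)':<34}"
        f"{example.pred_cbt:>10.1f}{example.pred_adm:>10.1f}"
    )
    lines.append("")
    lines.append(
        f"PAI = {example.pai:.1f}, favoring {example.prediction.optimal_arm}"
    )
    return "\n".join(lines)
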