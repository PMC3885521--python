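"""Design construction, OLS fitting, leave-one-out counterfactual prediction.

The model on the transformed outcome z is

    z = b0 + sum_j b_j x_j + b_T T + sum_{k in prescriptive} g_k (T * x_k) + e

with T coded +1/2 for the first-listed arm and -1/2 for the second.  Each
patient's factual and counterfactual endpoints are predicted from a model
fit on the other n-1 patients (leave-one-out), so predictions carry no
information from the patient's own outcome; the counterfactual is obtained
by flipping the sign of the treatment code in the treatment main effect and
every interaction term.  The Personalized Advantage Index (PAI) is the
absolute difference between the two arm-specific predicted endpoints, in
outcome units.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    DesignRow,
    ModelFit,
    PAIError,
    PatientPrediction,
    PatientRecord,
    RankDeficiencyError,
    SchemaError,
    TrialDataset,
)
from .preprocessing import back_transform, encode_value, resolve_centers, transform_outcome

INTERCEPT = "intercept"
TREATMENT = "treatment"


def term_names(dataset: TrialDataset) -> tuple[str, ...]:
    """Ordered model terms: intercept, mains, treatment, interactions."""
    names = [INTERCEPT]
    names += [s.name for s in dataset.prognostic_specs]
    names += [s.name for s in dataset.prescriptive_specs]
    names.append(TREATMENT)
    names += [f"{TREATMENT}:{s.name}" for s in dataset.prescriptive_specs]
    return tuple(names)


def build_design_row(
    record: PatientRecord,
    dataset: TrialDataset,
    arm: str,
    centers: Mapping[str, float],
) -> DesignRow:
    """Code one patient's covariates into a design row under a given arm.

    Calling with the other arm flips the sign of the treatment entry and of
    every interaction entry, leaving mains untouched -- this is exactly the
    counterfactual substitution.
    """
    tx = dataset.treatment_code(arm)
    values = [1.0]
    mains: dict[str, float] = {}
    for spec in list(dataset.prognostic_specs) + list(dataset.prescriptive_specs):
        try:
            raw = record.covariates[spec.name]
        except KeyError:
            raise SchemaError(
                f"patient {record.patient_id!r}: missing covariate {spec.name!r}"
            ) from None
        coded = encode_value(spec, raw, centers.get(spec.name))
        mains[spec.name] = coded
        values.append(coded)
    values.append(tx)
    for spec in dataset.prescriptive_specs:
        values.append(tx * mains[spec.name])
    return DesignRow(term_names=term_names(dataset), values=tuple(values))


def fit_linear_model(
    rows: Sequence[DesignRow],
    z: Sequence[float],
    excluded_patient_id: Optional[str] = None,
) -> ModelFit:
    """Exact least-squares fit of the interaction model.

    Raises :class:`RankDeficiencyError` naming the collinear terms when the
    design is not of full column rank, and a :class:`PAIError` when there
    are not strictly more observations than terms.
    """
    if not rows:
        raise PAIError("no design rows to fit")
    names = rows[0].term_names
    X = np.array([r.values for r in rows], dtype=float)
    y = np.asarray(z, dtype=float)
    n, p = X.shape
    if n <= p:
        raise PAIError(f"cannot fit: n={n} observations for p={p} terms")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        collinear = _collinear_terms(X, names)
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {p} terms; collinear terms: "
            f"{collinear}",
            collinear_terms=collinear,
        )
    resid = y - X @ beta
    residual_sd = float(np.sqrt(resid @ resid / (n - p)))
    return ModelFit(
        coefficients=dict(zip(names, beta.tolist())),
        n_fit=n,
        residual_sd=residual_sd,
        excluded_patient_id=excluded_patient_id,
    )


def _collinear_terms(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Identify terms involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    dropped = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    return dropped or list(names)


def compute_pai(
    pred_by_arm: Mapping[str, float], better_direction: str = "lower"
) -> tuple[float, str]:
    """PAI and Optimal arm from the two arm-specific predicted endpoints.

    Returns ``(pai, optimal_arm)`` where ``pai = |difference|`` and the
    Optimal arm has the strictly better prediction ("none" on an exact tie).
    """
    if len(pred_by_arm) != 2:
        raise PAIError("exactly two arm predictions required")
    (arm_a, pred_a), (arm_b, pred_b) = pred_by_arm.items()
    if not (np.isfinite(pred_a) and np.isfinite(pred_b)):
        raise PAIError(f"non-finite prediction: {dict(pred_by_arm)!r}")
    pai = abs(pred_a - pred_b)
    if pred_a == pred_b:
        return 0.0, "none"
    if better_direction == "lower":
        optimal = arm_a if pred_a < pred_b else arm_b
    else:
        optimal = arm_a if pred_a > pred_b else arm_b
    return float(pai), optimal


def _predict_patient(
    fit: ModelFit,
    record: PatientRecord,
    dataset: TrialDataset,
    centers: Mapping[str, float],
) -> PatientPrediction:
    pred_by_arm = {}
    for arm in dataset.arms:
        row = build_design_row(record, dataset, arm, centers)
        pred_by_arm[arm] = back_transform(
            fit.predict_row(row), dataset.outcome_transform
        )
    pai, optimal = compute_pai(pred_by_arm, dataset.better_direction)
    if optimal == "none":
        received = "indeterminate"
    else:
        received = "true" if record.arm == optimal else "false"
    return PatientPrediction(
        patient_id=record.patient_id,
        pred_by_arm=pred_by_arm,
        factual_arm=record.arm,
        pai=pai,
        optimal_arm=optimal,
        received_optimal=received,
        observed_endpoint=record.observed_endpoint,
    )


def loo_predict(
    dataset: TrialDataset, centering: str = "full"
) -> list[PatientPrediction]:
    """Leave-one-out factual and counterfactual predictions for all patients.

    For each patient i the model is fit on the other n-1 patients and i's
    endpoint is predicted under both arms; the fitting model never sees
    patient i's outcome.

    Parameters
    ----------
    dataset : TrialDataset
    centering : {"full", "per_fold"}
        Where "auto" centering constants are resolved: once on the full
        sample, or inside each training fold (strict leakage avoidance;
        predictions are invariant to this choice because shifted interaction
        columns stay within the span of the included mains and treatment
        column, but residual SDs differ slightly).
    """
    if centering not in ("full", "per_fold"):
        raise SchemaError("centering must be 'full' or 'per_fold'")
    dataset.require_outcomes()
    if not dataset.prescriptive_specs:
        raise SchemaError("at least one prescriptive variable required for PAI")
    records = list(dataset.records)
    raw_cols = {
        s.name: np.array([float_or_nan(r.covariates[s.name]) for r in records])
        for s in dataset.specs
        if s.kind in ("continuous", "capped_count")
    }
    full_centers = resolve_centers(dataset.specs, raw_cols)
    z_all = [
        transform_outcome(r.observed_endpoint, dataset.outcome_transform)
        for r in records
    ]
    predictions = []
    for i, record in enumerate(records):
        train = [r for j, r in enumerate(records) if j != i]
        if centering == "per_fold":
            cols = {k: np.delete(v, i) for k, v in raw_cols.items()}
            centers = resolve_centers(dataset.specs, cols)
        else:
            centers = full_centers
        rows = [build_design_row(r, dataset, r.arm, centers) for r in train]
        z = [zv for j, zv in enumerate(z_all) if j != i]
        try:
            fit = fit_linear_model(rows, z, excluded_patient_id=record.patient_id)
        except RankDeficiencyError as err:
            raise RankDeficiencyError(
                f"fold excluding patient {record.patient_id!r}: {err}",
                collinear_terms=err.collinear_terms,
            ) from err
        predictions.append(_predict_patient(fit, record, dataset, centers))
    return predictions


def fit_full_sample(dataset: TrialDataset) -> ModelFit:
    """OLS fit on all patients (no exclusion), for coefficient reporting."""
    dataset.require_outcomes()
    records = list(dataset.records)
    raw_cols = {
        s.name: np.array([float_or_nan(r.covariates[s.name]) for r in records])
        for s in dataset.specs
        if s.kind in ("continuous", "capped_count")
    }
    centers = resolve_centers(dataset.specs, raw_cols)
    rows = [build_design_row(r, dataset, r.arm, centers) for r in records]
    z = [
        transform_outcome(r.observed_endpoint, dataset.outcome_transform)
        for r in records
    ]
    return fit_linear_model(rows, z)


def float_or_nan(value: object) -> float:
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return float("nan")
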