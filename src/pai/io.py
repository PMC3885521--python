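"""CSV / YAML input-output: trial tables, variable configs, predictions.

Trial data arrive as one CSV row per patient (patient id, arm, one column
per covariate, outcome); variable roles and codings come from a YAML or
JSON config keyed by column name.  Predictions are written at 4 decimal
places (readable tables); summaries are written as JSON at full precision
with sorted keys, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .data_model import (
    PatientPrediction,
    PatientRecord,
    SchemaError,
    TrialDataset,
    VariableSpec,
)


def load_variable_config(path: str | Path) -> dict:
    """Parse and validate a variable-role config (YAML or JSON).

    Expected structure::

        arms: [CBT, ADM]            # first-listed arm coded +1/2
        outcome: {column: end_hrsd, transform: sqrt}
        better_direction: lower     # optional
        variables:
          intake_hrsd: {role: prognostic, kind: continuous, center: auto}
          married:     {role: prescriptive, kind: binary,
                        positive_label: married, negative_label: unmarried}
          prior_adm_trials: {role: prescriptive, kind: capped_count, cap: 2}
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    for key in ("arms", "outcome", "variables"):
        if key not in cfg:
            raise SchemaError(f"{path}: missing config key {key!r}")
    if not isinstance(cfg["variables"], dict) or not cfg["variables"]:
        raise SchemaError(f"{path}: 'variables' must be a non-empty mapping")
    return cfg


def specs_from_config(cfg: dict) -> list[VariableSpec]:
    specs = []
    for name, v in cfg["variables"].items():
        if not isinstance(v, dict) or "role" not in v or "kind" not in v:
            raise SchemaError(
                f"variable {name!r}: config needs at least 'role' and 'kind'"
            )
        center = v.get("center", "auto")
        specs.append(
            VariableSpec(
                name=name,
                role=v["role"],
                kind=v["kind"],
                binary_positive_label=v.get("positive_label"),
                binary_negative_label=v.get("negative_label"),
                cap=v.get("cap"),
                centering_constant="auto" if center == "auto" else center
                if v["kind"] in ("continuous", "capped_count") else "auto",
            )
        )
    return specs


def load_trial(
    data_path: str | Path,
    config_path: str | Path,
    require_outcome: bool = True,
) -> TrialDataset:
    """Load and validate a trial CSV against its variable config.

    Schema violations are reported with row and column coordinates.  With
    ``require_outcome=True`` (fit mode) every patient needs a numeric,
    nonnegative outcome; otherwise the outcome column may be absent or
    empty (predict-only use).
    """
    data_path = Path(data_path)
    if not data_path.exists():
        raise SchemaError(f"data file not found: {data_path}")
    cfg = load_variable_config(config_path)
    specs = specs_from_config(cfg)
    outcome_col = cfg["outcome"]["column"]
    transform = cfg["outcome"].get("transform", "sqrt")
    arms = tuple(cfg["arms"])
    df = pd.read_csv(data_path, dtype={"patient_id": str})
    if df.empty:
        raise SchemaError(f"{data_path}: no patient rows")
    required = ["patient_id", "arm"] + [s.name for s in specs]
    if require_outcome:
        required.append(outcome_col)
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{data_path}: missing column(s) {missing_cols}")
    records = []
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        covariates = {}
        for spec in specs:
            value = row[spec.name]
            if pd.isna(value):
                raise SchemaError(
                    f"{data_path} row {idx + 2}, column {spec.name!r}: "
                    "missing value (complete cases required)"
                )
            if spec.kind in ("continuous", "capped_count"):
                try:
                    value = float(value)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"{data_path} row {idx + 2}, column {spec.name!r}: "
                        f"non-numeric value {value!r}"
                    ) from None
            covariates[spec.name] = value
        endpoint = None
        if outcome_col in df.columns and not pd.isna(row.get(outcome_col)):
            try:
                endpoint = float(row[outcome_col])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{data_path} row {idx + 2}, column {outcome_col!r}: "
                    f"non-numeric outcome {row[outcome_col]!r}"
                ) from None
        if require_outcome and endpoint is None:
            raise SchemaError(
                f"{data_path} row {idx + 2}: missing outcome "
                f"{outcome_col!r} (fit mode requires complete cases)"
            )
        try:
            records.append(
                PatientRecord(
                    patient_id=pid,
                    arm=str(row["arm"]),
                    covariates=covariates,
                    observed_endpoint=endpoint,
                )
            )
        except SchemaError as err:
            raise SchemaError(f"{data_path} row {idx + 2}: {err}") from None
    try:
        return TrialDataset(
            records=records,
            arms=arms,
            specs=specs,
            outcome_transform=transform,
            better_direction=cfg.get("better_direction", "lower"),
            outcome_name=outcome_col,
        )
    except SchemaError as err:
        raise SchemaError(f"{data_path}: {err}") from None


def trial_to_frame(dataset: TrialDataset) -> pd.DataFrame:
    """Serialize a TrialDataset back to one row per patient."""
    rows = []
    for rec in dataset.records:
        row = {"patient_id": rec.patient_id, "arm": rec.arm}
        row.update(rec.covariates)
        row[dataset.outcome_name] = rec.observed_endpoint
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    trial_to_frame(dataset).to_csv(path, index=False, float_format="%.4f")


def config_from_dataset(dataset: TrialDataset) -> dict:
    """Variable-role config mirroring a dataset (e.g. a synthetic one)."""
    variables = {}
    for s in dataset.specs:
        v: dict = {"role": s.role, "kind": s.kind}
        if s.kind == "binary":
            v["positive_label"] = s.binary_positive_label
            if s.binary_negative_label is not None:
                v["negative_label"] = s.binary_negative_label
        if s.kind == "capped_count":
            v["cap"] = int(s.cap)
        if s.kind in ("continuous", "capped_count"):
            v["center"] = s.centering_constant if s.centering_constant != "auto" else "auto"
        variables[s.name] = v
    return {
        "arms": list(dataset.arms),
        "outcome": {"column": dataset.outcome_name, "transform": dataset.outcome_transform},
        "better_direction": dataset.better_direction,
        "variables": variables,
    }


def write_variable_config(dataset: TrialDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_from_dataset(dataset), fh, sort_keys=False)


def predictions_to_frame(
    predictions: Sequence[PatientPrediction], arms: Sequence[str]
) -> pd.DataFrame:
    arm_a, arm_b = arms
    rows = []
    for p in predictions:
        rows.append(
            {
                "patient_id": p.patient_id,
                "arm_received": p.factual_arm,
                f"pred_{arm_a}": p.pred_by_arm[arm_a],
                f"pred_{arm_b}": p.pred_by_arm[arm_b],
                "pai": p.pai,
                "optimal_arm": p.optimal_arm,
                "received_optimal": p.received_optimal,
            }
        )
    return pd.DataFrame(rows)


def write_predictions_csv(
    predictions: Sequence[PatientPrediction],
    arms: Sequence[str],
    path: str | Path,
) -> None:
    predictions_to_frame(predictions, arms).to_csv(
        path, index=False, float_format="%.4f"
    )


def read_predictions_csv(
    path: str | Path, dataset: Optional[TrialDataset] = None
) -> list[PatientPrediction]:
    """Reload a predictions CSV, optionally joining observed endpoints."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"predictions file not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    if len(pred_cols) != 2:
        raise SchemaError(
            f"{path}: expected exactly two pred_<arm> columns, got {pred_cols}"
        )
    arms = [c[len("pred_"):] for c in pred_cols]
    observed = {}
    if dataset is not None:
        observed = {r.patient_id: r.observed_endpoint for r in dataset.records}
    preds = []
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        preds.append(
            PatientPrediction(
                patient_id=pid,
                pred_by_arm={arms[0]: float(row[pred_cols[0]]),
                             arms[1]: float(row[pred_cols[1]])},
                factual_arm=str(row["arm_received"]),
                pai=float(row["pai"]),
                optimal_arm=str(row["optimal_arm"]),
                received_optimal=str(row["received_optimal"]).lower(),
                observed_endpoint=observed.get(pid),
            )
        )
    return preds


def write_summary_json(report: dict, path: str | Path) -> None:
    from .evaluation import report_to_json

    Path(path).write_text(report_to_json(report) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
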