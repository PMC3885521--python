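"""Independent brute-force oracle for the LOO counterfactual pipeline.

Deliberately a separate code path from the package: covariates are coded
with local dict-based logic into a pandas DataFrame, each leave-one-out
fold is refit with statsmodels OLS, and the counterfactual design is built
from scratch for the held-out patient under each arm.  Used only to verify
the engine; never imported by the package.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pai.data_model import TrialDataset


def _code_column(spec, raw_values, centers):
    kind = spec.kind
    if kind == "binary":
        return np.array(
            [0.5 if v == spec.binary_positive_label else -0.5 for v in raw_values]
        )
    if kind == "ordinal3":
        m = {"low": -1.0, "middle": 0.0, "high": 1.0}
        return np.array([m[str(v).strip().lower()] for v in raw_values])
    vals = np.array([float(v) for v in raw_values])
    if kind == "capped_count":
        vals = np.minimum(vals, float(spec.cap))
    return vals - centers[spec.name]


def _centers(dataset: TrialDataset, exclude_index=None):
    centers = {}
    for spec in dataset.specs:
        if spec.kind not in ("continuous", "capped_count"):
            continue
        if spec.centering_constant not in ("auto", None):
            centers[spec.name] = float(spec.centering_constant)
            continue
        vals = [float(r.covariates[spec.name]) for i, r in enumerate(dataset.records)
                if i != exclude_index]
        vals = np.asarray(vals)
        if spec.kind == "capped_count":
            vals = np.minimum(vals, float(spec.cap))
        centers[spec.name] = float(vals.mean())
    return centers


def _design_frame(dataset: TrialDataset, centers, arm_override=None):
    ordered = list(dataset.prognostic_specs) + list(dataset.prescriptive_specs)
    cols = {"const": np.ones(len(dataset.records))}
    for spec in ordered:
        raw = [r.covariates[spec.name] for r in dataset.records]
        cols[spec.name] = _code_column(spec, raw, centers)
    arms = [arm_override or r.arm for r in dataset.records]
    tx = np.array([0.5 if a == dataset.arms[0] else -0.5 for a in arms])
    cols["treatment"] = tx
    for spec in dataset.prescriptive_specs:
        cols[f"treatment:{spec.name}"] = tx * cols[spec.name]
    return pd.DataFrame(cols)


def loo_predict_oracle(dataset: TrialDataset, centering: str = "full"):
    """Per-patient refit with statsmodels; returns dict per patient:
    {arm: predicted endpoint}, pai, optimal arm."""
    n = len(dataset.records)
    z = np.array(
        [math.sqrt(r.observed_endpoint) if dataset.outcome_transform == "sqrt"
         else r.observed_endpoint for r in dataset.records]
    )
    out = []
    for i in range(n):
        centers = _centers(dataset, exclude_index=i if centering == "per_fold" else None)
        X = _design_frame(dataset, centers)
        train_idx = [j for j in range(n) if j != i]
        fit = sm.OLS(z[train_idx], X.iloc[train_idx]).fit()
        preds = {}
        for arm in dataset.arms:
            Xa = _design_frame(dataset, centers, arm_override=arm)
            zi = float(fit.predict(Xa.iloc[[i]]).iloc[0])
            if dataset.outcome_transform == "sqrt":
                preds[arm] = max(zi, 0.0) ** 2
            else:
                preds[arm] = zi
        pa, pb = preds[dataset.arms[0]], preds[dataset.arms[1]]
        pai = abs(pa - pb)
        if pa == pb:
            optimal = "none"
        else:
            optimal = dataset.arms[0] if pa < pb else dataset.arms[1]
        out.append({"pred_by_arm": preds, "pai": pai, "optimal_arm": optimal})
    return out
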