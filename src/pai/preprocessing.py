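"""Kraemer-convention coding, outcome transformation, residual diagnostics.

Dichotomous covariates (and the treatment indicator) are coded +-1/2,
3-level ordinals -1/0/+1, counts are capped then mean-centered, continuous
covariates mean-centered.  Centering at the sample mean makes the treatment
main effect interpretable as the average treatment effect at the mean
covariate profile, and keeps interaction columns near-orthogonal to mains.

The severity outcome is square-root transformed before fitting (variance-
stabilizing for the skewed end-of-treatment score distributions seen on
scales such as the HRSD); model output is squared back, clamping negative
linear predictions to zero because the scale is bounded below.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .data_model import SchemaError, VariableSpec


def encode_binary(raw: object, spec: VariableSpec) -> float:
    """Map a dichotomous category to +0.5 (positive label) or -0.5."""
    if raw == spec.binary_positive_label:
        return 0.5
    if spec.binary_negative_label is None or raw == spec.binary_negative_label:
        if spec.binary_negative_label is None and isinstance(raw, float) and math.isnan(raw):
            raise SchemaError(f"variable {spec.name!r}: missing value")
        return -0.5
    raise SchemaError(
        f"variable {spec.name!r}: unknown category {raw!r} (expected "
        f"{spec.binary_positive_label!r} or {spec.binary_negative_label!r})"
    )


_ORDINAL3 = {"low": -1.0, "middle": 0.0, "high": 1.0}


def encode_ordinal3(raw: object) -> float:
    """Map a low/middle/high band to -1/0/+1 (case-insensitive)."""
    key = str(raw).strip().lower()
    if key not in _ORDINAL3:
        raise SchemaError(
            f"unknown ordinal band {raw!r}: expected low, middle or high"
        )
    return _ORDINAL3[key]


def cap_count(raw: float, cap: int) -> int:
    """min(raw, cap) for a nonnegative integer count."""
    value = int(raw)
    if value < 0:
        raise SchemaError(f"count must be >= 0, got {raw!r}")
    if cap < 0:
        raise SchemaError(f"cap must be >= 0, got {cap!r}")
    return min(value, int(cap))


def center_continuous(raw: float, centering_constant: float) -> float:
    """Subtract a fixed centering constant."""
    raw = float(raw)
    c = float(centering_constant)
    if not (math.isfinite(raw) and math.isfinite(c)):
        raise SchemaError(
            f"non-finite value in centering: raw={raw!r}, constant={c!r}"
        )
    return raw - c


def encode_value(spec: VariableSpec, raw: object, center: float | None = None) -> float:
    """Code one raw covariate value per its spec.

    ``center`` is the resolved centering constant for continuous /
    capped-count variables (capping happens before centering).
    """
    if spec.kind == "binary":
        return encode_binary(raw, spec)
    if spec.kind == "ordinal3":
        return encode_ordinal3(raw)
    if spec.kind == "capped_count":
        capped = cap_count(float(raw), int(spec.cap))
        if center is None:
            raise SchemaError(f"variable {spec.name!r}: centering constant unresolved")
        return center_continuous(capped, center)
    # continuous
    if center is None:
        raise SchemaError(f"variable {spec.name!r}: centering constant unresolved")
    return center_continuous(float(raw), center)


def resolve_centers(
    specs: Iterable[VariableSpec],
    raw_columns: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Resolve "auto" centering constants as fitting-sample means.

    For capped counts the mean is taken after capping, so the constant is
    the mean of the variable actually entering the model.
    """
    centers: dict[str, float] = {}
    for spec in specs:
        if spec.kind in ("binary", "ordinal3"):
            continue
        if spec.centering_constant == "auto" or spec.centering_constant is None:
            col = np.asarray(raw_columns[spec.name], dtype=float)
            if spec.kind == "capped_count":
                col = np.minimum(col, float(spec.cap))
            centers[spec.name] = float(col.mean())
        else:
            centers[spec.name] = float(spec.centering_constant)
    return centers


def transform_outcome(y: float, transform: str = "sqrt") -> float:
    """Map an observed endpoint to the model scale."""
    y = float(y)
    if transform == "identity":
        return y
    if transform != "sqrt":
        raise SchemaError(f"unknown transform {transform!r}")
    if y < 0:
        raise SchemaError(f"endpoint must be >= 0 for sqrt transform, got {y!r}")
    return math.sqrt(y)


def back_transform(z: float, transform: str = "sqrt") -> float:
    """Map a model-scale prediction back to outcome units.

    Negative linear predictions on the square-root scale clamp to 0 before
    squaring: the outcome scale is bounded below at zero.
    """
    z = float(z)
    if transform == "identity":
        return z
    if transform != "sqrt":
        raise SchemaError(f"unknown transform {transform!r}")
    return max(z, 0.0) ** 2


def residual_normality_check(residuals) -> tuple[float, float, str]:
    """Shapiro-Wilk omnibus normality test on model residuals.

    Returns ``(statistic, p_value, verdict)`` with verdict "non-normal"
    when p < 0.05, else "normal".  Reported as a diagnostic only, never
    blocking: it motivates (or questions) the square-root transform.
    """
    res = np.asarray(residuals, dtype=float)
    if res.size < 3:
        raise SchemaError("need at least 3 residuals for a normality test")
    if np.ptp(res) == 0.0:
        raise SchemaError("residuals are constant: normality test undefined")
    stat, p = stats.shapiro(res)
    verdict = "non-normal" if p < 0.05 else "normal"
    return float(stat), float(p), verdict
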