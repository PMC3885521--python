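"""Domain types shared by every stage of the PAI pipeline.

The package analyzes two-arm randomized trials with a continuous
end-of-treatment severity outcome (e.g. the Hamilton Rating Scale for
Depression, HRSD, where lower is better).  Baseline covariates are declared
either *prognostic* (predict outcome irrespective of treatment; main effect
only) or *prescriptive* (moderators; main effect plus a treatment
interaction).  These declarations, together with each variable's coding,
live in :class:`VariableSpec`; a full trial is a :class:`TrialDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


class PAIError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PAIError):
    """Invalid input data or configuration."""


class RankDeficiencyError(PAIError):
    """The design matrix of a model fit is not of full column rank."""

    def __init__(self, message: str, collinear_terms: Sequence[str] = ()):
        super().__init__(message)
        self.collinear_terms = list(collinear_terms)


class EvaluationError(PAIError):
    """The Optimal/Non-optimal comparison cannot be carried out."""


VALID_ROLES = ("prognostic", "prescriptive")
VALID_KINDS = ("continuous", "binary", "ordinal3", "capped_count")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one baseline covariate.

    Parameters
    ----------
    name : str
        Column name in the trial table.
    role : {"prognostic", "prescriptive"}
        Prognostic variables enter the model as main effects only;
        prescriptive variables additionally get a treatment interaction.
    kind : {"continuous", "binary", "ordinal3", "capped_count"}
        Coding convention.  Binary variables are dummy-coded +-1/2, 3-level
        ordinals -1/0/+1, counts are capped then mean-centered, continuous
        variables are mean-centered.
    binary_positive_label : str, optional
        The category mapped to +0.5 (binary only).
    binary_negative_label : str, optional
        The category mapped to -0.5 (binary only).  If omitted, any other
        observed label is rejected as unknown unless exactly one other
        category occurs -- safer to declare it.
    cap : int, optional
        Upper cap applied to raw counts before centering (capped_count only).
    centering_constant : float or "auto"
        Constant subtracted from continuous / capped-count values.  "auto"
        means: use the mean of the fitting sample (capped first for counts).
    """

    name: str
    role: str
    kind: str
    binary_positive_label: Optional[str] = None
    binary_negative_label: Optional[str] = None
    cap: Optional[int] = None
    centering_constant: object = "auto"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise SchemaError(
                f"variable {self.name!r}: role must be one of {VALID_ROLES}, "
                f"got {self.role!r}"
            )
        if self.kind not in VALID_KINDS:
            raise SchemaError(
                f"variable {self.name!r}: kind must be one of {VALID_KINDS}, "
                f"got {self.kind!r}"
            )
        if self.kind == "capped_count":
            if self.cap is None or int(self.cap) < 0:
                raise SchemaError(
                    f"variable {self.name!r}: capped_count requires a "
                    f"nonnegative integer cap, got {self.cap!r}"
                )
        elif self.cap is not None:
            raise SchemaError(
                f"variable {self.name!r}: cap is only valid for capped_count"
            )
        if self.kind == "binary":
            if self.binary_positive_label is None:
                raise SchemaError(
                    f"variable {self.name!r}: binary requires "
                    "binary_positive_label"
                )
        elif self.binary_positive_label is not None:
            raise SchemaError(
                f"variable {self.name!r}: binary_positive_label is only "
                "valid for binary variables"
            )
        if self.kind in ("binary", "ordinal3") and self.centering_constant not in (
            "auto",
            None,
        ):
            raise SchemaError(
                f"variable {self.name!r}: centering_constant applies only to "
                "continuous/capped_count variables"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: arm received, raw covariates, observed endpoint.

    ``observed_endpoint`` may be ``None`` for predict-only use; when present
    it must be >= 0 (severity scales are bounded below at zero).
    """

    patient_id: str
    arm: str
    covariates: Mapping[str, object]
    observed_endpoint: Optional[float] = None

    def __post_init__(self) -> None:
        if self.observed_endpoint is not None and not (
            float(self.observed_endpoint) >= 0.0
        ):
            raise SchemaError(
                f"patient {self.patient_id!r}: observed endpoint must be "
                f">= 0, got {self.observed_endpoint!r}"
            )


@dataclass
class TrialDataset:
    """A two-arm randomized trial ready for model fitting.

    ``arms`` is an ordered pair of labels; the first-listed arm is coded
    +1/2 and the second -1/2 (the Kraemer convention).  ``better_direction``
    declares whether a lower or higher endpoint is the better outcome;
    severity scales such as the HRSD use the default "lower".
    """

    records: Sequence[PatientRecord]
    arms: Sequence[str]
    specs: Sequence[VariableSpec]
    outcome_transform: str = "sqrt"
    better_direction: str = "lower"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        arms = tuple(self.arms)
        if len(arms) != 2 or arms[0] == arms[1]:
            raise SchemaError(
                f"exactly two distinct arm labels required, got {arms!r}"
            )
        self.arms = arms
        if self.outcome_transform not in ("sqrt", "identity"):
            raise SchemaError(
                "outcome_transform must be 'sqrt' or 'identity', got "
                f"{self.outcome_transform!r}"
            )
        if self.better_direction not in ("lower", "higher"):
            raise SchemaError(
                "better_direction must be 'lower' or 'higher'"
            )
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in specs")
        for rec in self.records:
            if rec.arm not in arms:
                raise SchemaError(
                    f"patient {rec.patient_id!r}: arm {rec.arm!r} is not one "
                    f"of {arms!r}"
                )
            missing = [n for n in names if n not in rec.covariates]
            if missing:
                raise SchemaError(
                    f"patient {rec.patient_id!r}: missing covariate(s) "
                    f"{missing} (complete cases required)"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def prescriptive_specs(self) -> list[VariableSpec]:
        return [s for s in self.specs if s.role == "prescriptive"]

    @property
    def prognostic_specs(self) -> list[VariableSpec]:
        return [s for s in self.specs if s.role == "prognostic"]

    def treatment_code(self, arm: str) -> float:
        """Kraemer +-1/2 code for an arm label."""
        if arm == self.arms[0]:
            return 0.5
        if arm == self.arms[1]:
            return -0.5
        raise SchemaError(f"unknown arm {arm!r}; expected one of {self.arms!r}")

    def require_outcomes(self) -> None:
        missing = [r.patient_id for r in self.records if r.observed_endpoint is None]
        if missing:
            raise SchemaError(
                f"patients without observed endpoint (fit mode requires "
                f"complete cases): {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )


@dataclass(frozen=True)
class DesignRow:
    """One row of the design matrix, with named terms.

    Order: intercept, prognostic mains, prescriptive mains, treatment,
    treatment x prescriptive interactions.
    """

    term_names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.term_names) != len(self.values):
            raise SchemaError("term_names and values lengths differ")
        if self.values[0] != 1.0:
            raise SchemaError("first design entry must be the intercept 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.term_names, self.values))


@dataclass(frozen=True)
class ModelFit:
    """OLS coefficients on the transformed-outcome scale."""

    coefficients: Mapping[str, float]
    n_fit: int
    residual_sd: float
    excluded_patient_id: Optional[str] = None

    def predict_row(self, row: DesignRow) -> float:
        """Linear predictor for one design row (transformed scale)."""
        coef = self.coefficients
        return float(sum(coef[t] * v for t, v in zip(row.term_names, row.values)))


@dataclass(frozen=True)
class PatientPrediction:
    """Factual and counterfactual predictions for one patient.

    All predicted endpoints are on the original outcome scale.  ``pai`` is
    the absolute difference between the two arm-specific predictions;
    ``optimal_arm`` is the arm with the strictly better prediction, or
    "none" on an exact tie, in which case ``received_optimal`` is
    "indeterminate".
    """

    patient_id: str
    pred_by_arm: Mapping[str, float]
    factual_arm: str
    pai: float
    optimal_arm: str
    received_optimal: str  # "true" | "false" | "indeterminate"
    observed_endpoint: Optional[float] = None

    @property
    def factual_prediction(self) -> float:
        return self.pred_by_arm[self.factual_arm]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison of observed endpoints, Optimal vs Non-optimal.

    ``mean_diff`` is Non-optimal mean minus Optimal mean, so a positive
    value favors assignment by the index when lower outcomes are better.
    ``cohens_d = mean_diff / pooled_sd`` with a 95% CI from noncentral-t
    inversion.
    """

    n_optimal: int
    n_nonoptimal: int
    mean_optimal: float
    mean_nonoptimal: float
    mean_diff: float
    pooled_sd: float
    t_stat: float
    df: int
    p_value: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float

    def __post_init__(self) -> None:
        if self.df != self.n_optimal + self.n_nonoptimal - 2:
            raise SchemaError("df must equal n_optimal + n_nonoptimal - 2")


def summarize_endpoint(series: Sequence[tuple[float, float]]) -> float:
    """Collapse a per-visit score series to a single endpoint.

    The endpoint is the mean of the final two scores in week order
    (smoothing single-visit fluctuation at the end of treatment); with a
    single visit, that score is returned unchanged.

    Parameters
    ----------
    series : sequence of (week, score)
        Visit week and nonnegative score.  Order does not matter.

    Returns
    -------
    float
    """
    if len(series) == 0:
        raise SchemaError("no outcome assessments: cannot summarize endpoint")
    for week, score in series:
        if not (float(score) >= 0.0):
            raise SchemaError(f"negative score {score!r} at week {week!r}")
    ordered = sorted(series, key=lambda ws: ws[0])
    last_two = ordered[-2:]
    return float(sum(s for _, s in last_two)) / len(last_two)
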