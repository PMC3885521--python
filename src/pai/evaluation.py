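"""Prediction-quality metrics and the Optimal vs Non-optimal comparison.

Because patients were randomized, those who happened to receive the arm the
index labels Optimal and those who received the other arm are exchangeable
at baseline; comparing their observed endpoints is an unbiased test of the
benefit of index-guided assignment.  The comparison is a pooled-variance
two-sample t-test with Cohen's d = mean difference / pooled SD and a 95%
CI for d obtained by inverting the noncentral-t distribution (the standard
exact interval for a standardized mean difference; unlike the normal
approximation it is asymmetric around d).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import (
    ComparisonResult,
    EvaluationError,
    PatientPrediction,
    SchemaError,
    TrialDataset,
)


def true_error(observed: Sequence[float], factual_pred: Sequence[float]) -> float:
    """Mean absolute difference between observed and factually predicted endpoints."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(factual_pred, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise SchemaError("observed and predicted vectors must match, length >= 1")
    return float(np.mean(np.abs(obs - pred)))


def se_prediction(observed: Sequence[float], factual_pred: Sequence[float]) -> float:
    """Root-mean-square prediction error, in outcome units.

    The RMSE is the default "standard error of prediction"; the sample SD
    of the errors is also available (:func:`sd_of_errors`) as an alternate
    definition.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(factual_pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise SchemaError("observed and predicted vectors must match, length >= 2")
    err = obs - pred
    return float(np.sqrt(np.mean(err**2)))


def sd_of_errors(observed: Sequence[float], factual_pred: Sequence[float]) -> float:
    """Sample standard deviation (ddof=1) of the prediction errors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(factual_pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise SchemaError("observed and predicted vectors must match, length >= 2")
    return float(np.std(obs - pred, ddof=1))


def split_by_threshold(
    predictions: Sequence[PatientPrediction], threshold: float
) -> tuple[list[PatientPrediction], list[PatientPrediction]]:
    """Partition patients by clinical significance of their PAI.

    The significant subset holds patients with ``pai >= threshold`` and a
    determinate Optimal arm; everyone else (small PAI or exact tie) falls
    in the non-significant subset.
    """
    if threshold < 0:
        raise SchemaError("threshold must be >= 0")
    significant, rest = [], []
    for p in predictions:
        if p.optimal_arm != "none" and p.pai >= threshold:
            significant.append(p)
        else:
            rest.append(p)
    return significant, rest


def cohens_d(mean_diff: float, pooled_sd: float) -> float:
    """Standardized mean difference: mean difference over pooled SD."""
    if pooled_sd <= 0:
        raise SchemaError("pooled SD must be positive")
    return float(mean_diff) / float(pooled_sd)


def cohens_d_ci(
    t_stat: float, n1: int, n2: int, confidence: float = 0.95
) -> tuple[float, float]:
    """CI for Cohen's d by inverting the noncentral-t distribution.

    Finds noncentrality parameters delta_lo, delta_hi such that the observed
    t is the (1+c)/2 and (1-c)/2 quantile respectively, then rescales by
    sqrt(1/n1 + 1/n2).
    """
    alpha = 1.0 - confidence
    df = n1 + n2 - 2
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    def _cdf(delta: float) -> float:
        # nct.cdf underflows to NaN at extreme noncentrality; the true cdf
        # is ~1 far below t_stat and ~0 far above (cdf decreases in delta)
        value = stats.nct.cdf(t_stat, df, delta)
        if np.isnan(value):
            return 1.0 if delta < t_stat else 0.0
        return float(value)

    def _solve(target: float) -> float:
        # delta such that P(T_{df,delta} <= t_stat) = target
        f = lambda d: _cdf(d) - target
        lo, hi = t_stat - 20.0, t_stat + 20.0
        while f(lo) < 0:
            lo -= 20.0
        while f(hi) > 0:
            hi += 20.0
        return optimize.brentq(f, lo, hi, xtol=1e-10)

    delta_lo = _solve(1.0 - alpha / 2.0)
    delta_hi = _solve(alpha / 2.0)
    return float(delta_lo * scale), float(delta_hi * scale)


def compare_groups(
    optimal_scores: Sequence[float],
    nonoptimal_scores: Sequence[float],
    welch: bool = False,
) -> ComparisonResult:
    """Pooled-variance t-test of Non-optimal minus Optimal observed endpoints.

    ``mean_diff`` is oriented so that a positive value favors index-guided
    assignment when lower outcomes are better.  ``welch=True`` switches the
    t/p to the unequal-variance test; d still uses the pooled SD.
    """
    opt = np.asarray(optimal_scores, dtype=float)
    non = np.asarray(nonoptimal_scores, dtype=float)
    if opt.size == 0 or non.size == 0:
        raise EvaluationError(
            "cannot evaluate: one of the Optimal/Non-optimal groups is empty"
        )
    n1, n2 = opt.size, non.size
    df = n1 + n2 - 2
    mean_diff = float(non.mean() - opt.mean())
    if df <= 0:
        raise EvaluationError("cannot evaluate: fewer than 3 patients in total")
    pooled_var = ((n1 - 1) * opt.var(ddof=1) + (n2 - 1) * non.var(ddof=1)) / df
    pooled_sd = float(np.sqrt(pooled_var))
    if pooled_sd == 0.0:
        raise EvaluationError("cannot evaluate: zero within-group variance")
    t_res = stats.ttest_ind(non, opt, equal_var=not welch)
    d = cohens_d(mean_diff, pooled_sd)
    # CI from the pooled-variance t even under welch (d is pooled-SD based)
    t_pooled = mean_diff / (pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    ci_low, ci_high = cohens_d_ci(t_pooled, n2, n1)
    return ComparisonResult(
        n_optimal=n1,
        n_nonoptimal=n2,
        mean_optimal=float(opt.mean()),
        mean_nonoptimal=float(non.mean()),
        mean_diff=mean_diff,
        pooled_sd=pooled_sd,
        t_stat=float(t_res.statistic),
        df=df,
        p_value=float(t_res.pvalue),
        cohens_d=float(d),
        d_ci_low=ci_low,
        d_ci_high=ci_high,
    )


def compare_optimal_nonoptimal(
    predictions: Sequence[PatientPrediction], welch: bool = False
) -> ComparisonResult:
    """Observed-endpoint comparison of patients randomized to their Optimal
    vs Non-optimal arm.  Tied patients (indeterminate) are excluded."""
    opt, non = [], []
    for p in predictions:
        if p.observed_endpoint is None:
            raise SchemaError(
                f"patient {p.patient_id!r} has no observed endpoint"
            )
        if p.received_optimal == "true":
            opt.append(p.observed_endpoint)
        elif p.received_optimal == "false":
            non.append(p.observed_endpoint)
    return compare_groups(opt, non, welch=welch)


@dataclass(frozen=True)
class BalanceResult:
    variable: str
    test: str  # "t" | "chi2" | "degenerate"
    statistic: Optional[float]
    p_value: Optional[float]
    note: str = ""


def baseline_balance(dataset: TrialDataset, welch: bool = False) -> list[BalanceResult]:
    """Arm-balance tests per baseline covariate.

    t-test for continuous and capped-count variables, chi-square for binary
    and 3-level ordinal variables.  Degenerate variables (constant, or an
    empty contingency row/column) are flagged, not fatal.
    """
    arm_a, arm_b = dataset.arms
    results = []
    for spec in dataset.specs:
        vals_a = [r.covariates[spec.name] for r in dataset.records if r.arm == arm_a]
        vals_b = [r.covariates[spec.name] for r in dataset.records if r.arm == arm_b]
        if spec.kind in ("continuous", "capped_count"):
            xa = np.asarray(vals_a, dtype=float)
            xb = np.asarray(vals_b, dtype=float)
            if spec.kind == "capped_count":
                xa = np.minimum(xa, float(spec.cap))
                xb = np.minimum(xb, float(spec.cap))
            if xa.size < 2 or xb.size < 2:
                results.append(
                    BalanceResult(spec.name, "degenerate", None, None,
                                  "fewer than 2 observations in an arm")
                )
                continue
            if np.std(xa) == 0 and np.std(xb) == 0 and xa.mean() == xb.mean():
                results.append(
                    BalanceResult(spec.name, "t", 0.0, 1.0, "constant in both arms")
                )
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
            results.append(BalanceResult(spec.name, "t", float(t), float(p)))
        else:
            if spec.kind == "binary":
                cats = [spec.binary_positive_label]
                neg = spec.binary_negative_label
                others = sorted(
                    {v for v in vals_a + vals_b if v != spec.binary_positive_label},
                    key=str,
                )
                cats += [neg] if neg is not None else others
            else:
                cats = ["low", "middle", "high"]
                vals_a = [str(v).strip().lower() for v in vals_a]
                vals_b = [str(v).strip().lower() for v in vals_b]
            table = np.array(
                [[sum(v == c for v in vals) for c in cats] for vals in (vals_a, vals_b)],
                dtype=float,
            )
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
                results.append(
                    BalanceResult(spec.name, "degenerate", None, None,
                                  "degenerate contingency table")
                )
                continue
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            results.append(BalanceResult(spec.name, "chi2", float(chi2), float(p)))
    return results


@dataclass
class EvaluationSummary:
    """Aggregate evaluation of one LOO prediction run."""

    n: int
    threshold: float
    true_error: float
    se_prediction: float
    sd_of_errors: float
    mean_pai: float
    sd_pai: float
    n_above_threshold: int
    n_below_threshold: int
    mean_pred_optimal: float
    mean_pred_nonoptimal: float
    full_sample: ComparisonResult
    significant_subsample: Optional[ComparisonResult]
    notes: list[str] = field(default_factory=list)


def evaluate_predictions(
    predictions: Sequence[PatientPrediction],
    threshold: float = 3.0,
    welch: bool = False,
) -> EvaluationSummary:
    """Full evaluation: error metrics, PAI distribution, group comparisons.

    ``threshold`` is the clinical-significance criterion on the PAI in
    outcome units (default 3 points, the NICE criterion for the HRSD).
    """
    preds = list(predictions)
    if not preds:
        raise SchemaError("no predictions to evaluate")
    for p in preds:
        if p.observed_endpoint is None:
            raise SchemaError(f"patient {p.patient_id!r} has no observed endpoint")
    observed = [p.observed_endpoint for p in preds]
    factual = [p.factual_prediction for p in preds]
    pais = np.array([p.pai for p in preds])
    sig, nonsig = split_by_threshold(preds, threshold)
    notes: list[str] = []
    full = compare_optimal_nonoptimal(preds, welch=welch)
    try:
        sub = compare_optimal_nonoptimal(sig, welch=welch) if sig else None
        if sub is None:
            notes.append("no patient met the PAI threshold")
    except EvaluationError as err:
        sub = None
        notes.append(f"significant-subsample comparison unavailable: {err}")
    # predicted endpoint under the Optimal vs Non-optimal arm, determinate only
    pred_opt, pred_non = [], []
    for p in preds:
        if p.optimal_arm == "none":
            continue
        other = [a for a in p.pred_by_arm if a != p.optimal_arm][0]
        pred_opt.append(p.pred_by_arm[p.optimal_arm])
        pred_non.append(p.pred_by_arm[other])
    return EvaluationSummary(
        n=len(preds),
        threshold=float(threshold),
        true_error=true_error(observed, factual),
        se_prediction=se_prediction(observed, factual),
        sd_of_errors=sd_of_errors(observed, factual),
        mean_pai=float(pais.mean()),
        sd_pai=float(pais.std(ddof=1)) if pais.size > 1 else 0.0,
        n_above_threshold=len(sig),
        n_below_threshold=len(nonsig),
        mean_pred_optimal=float(np.mean(pred_opt)) if pred_opt else float("nan"),
        mean_pred_nonoptimal=float(np.mean(pred_non)) if pred_non else float("nan"),
        full_sample=full,
        significant_subsample=sub,
        notes=notes,
    )


def _comparison_dict(c: Optional[ComparisonResult]) -> Optional[dict]:
    if c is None:
        return None
    return {
        "n_optimal": c.n_optimal,
        "n_nonoptimal": c.n_nonoptimal,
        "mean_optimal": c.mean_optimal,
        "mean_nonoptimal": c.mean_nonoptimal,
        "mean_diff": c.mean_diff,
        "pooled_sd": c.pooled_sd,
        "t_stat": c.t_stat,
        "df": c.df,
        "p_value": c.p_value,
        "cohens_d": c.cohens_d,
        "d_ci_low": c.d_ci_low,
        "d_ci_high": c.d_ci_high,
    }


def build_report(
    predictions: Sequence[PatientPrediction],
    summary: EvaluationSummary,
    bin_width: float = 1.0,
    metadata: Optional[dict] = None,
) -> dict:
    """Machine-readable report: summary plus histogram data.

    Histograms cover the predicted endpoint under the Optimal and
    Non-optimal arm (determinate patients) and the PAI distribution over
    all patients; bin counts sum to the respective patient counts.
    """
    preds = list(predictions)
    if not preds:
        raise SchemaError("no predictions to report")

    def _hist(values: Sequence[float]) -> dict:
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            return {"bin_edges": [], "counts": []}
        top = max(np.ceil(vals.max() / bin_width) * bin_width, bin_width)
        edges = np.arange(0.0, top + bin_width / 2, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        return {"bin_edges": edges.tolist(), "counts": counts.tolist()}

    pred_opt, pred_non = [], []
    for p in preds:
        if p.optimal_arm == "none":
            continue
        other = [a for a in p.pred_by_arm if a != p.optimal_arm][0]
        pred_opt.append(p.pred_by_arm[p.optimal_arm])
        pred_non.append(p.pred_by_arm[other])
    report = {
        "summary": {
            "n": summary.n,
            "threshold": summary.threshold,
            "true_error": summary.true_error,
            "se_prediction": summary.se_prediction,
            "sd_of_errors": summary.sd_of_errors,
            "mean_pai": summary.mean_pai,
            "sd_pai": summary.sd_pai,
            "n_above_threshold": summary.n_above_threshold,
            "n_below_threshold": summary.n_below_threshold,
            "mean_pred_optimal": summary.mean_pred_optimal,
            "mean_pred_nonoptimal": summary.mean_pred_nonoptimal,
            "full_sample": _comparison_dict(summary.full_sample),
            "significant_subsample": _comparison_dict(summary.significant_subsample),
            "notes": summary.notes,
        },
        "histograms": {
            "predicted_optimal": _hist(pred_opt),
            "predicted_nonoptimal": _hist(pred_non),
            "pai": _hist([p.pai for p in preds]),
        },
    }
    if metadata:
        report["metadata"] = metadata
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, full float precision)."""
    return json.dumps(report, sort_keys=True, indent=2)
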