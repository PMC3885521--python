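"""statsmodels-style facade: ``PAIModel`` fits, ``PAIResults`` reports.

Typical use::

    from pai import PAIModel, SyntheticConfig, generate_trial

    dataset = generate_trial(SyntheticConfig(seed=7))
    results = PAIModel(dataset).fit()
    print(results.summary())
    evaluation = results.evaluate(threshold=3.0)
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ModelFit,
    PatientPrediction,
    PatientRecord,
    SchemaError,
    TrialDataset,
    VariableSpec,
)
from .engine import fit_full_sample, loo_predict
from .evaluation import (
    EvaluationSummary,
    baseline_balance,
    build_report,
    evaluate_predictions,
)
from .preprocessing import residual_normality_check, transform_outcome


class PAIModel:
    """Personalized Advantage Index model for a two-arm randomized trial.

    Fits a linear model on the (optionally square-root transformed)
    endpoint with main effects for all declared baseline covariates, a
    treatment main effect and treatment x prescriptive interactions, then
    produces leave-one-out factual and counterfactual predictions per
    patient.

    Parameters
    ----------
    dataset : TrialDataset
        Validated trial data; build one directly, via
        :meth:`from_dataframe`, or via :func:`pai.io.load_trial`.
    """

    def __init__(self, dataset: TrialDataset):
        if not dataset.prescriptive_specs:
            raise SchemaError(
                "PAI requires at least one prescriptive variable"
            )
        self.dataset = dataset

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        specs: Sequence[VariableSpec],
        arms: Sequence[str],
        outcome: str,
        transform: str = "sqrt",
        better_direction: str = "lower",
        patient_id: str = "patient_id",
        arm: str = "arm",
    ) -> "PAIModel":
        """Build a model from a per-patient DataFrame.

        ``outcome`` names the endpoint column; ``arms`` orders the two arm
        labels (first-listed coded +1/2).
        """
        required = [patient_id, arm, outcome] + [s.name for s in specs]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise SchemaError(f"dataframe missing column(s) {missing}")
        records = []
        for idx, row in data.iterrows():
            endpoint = row[outcome]
            records.append(
                PatientRecord(
                    patient_id=str(row[patient_id]),
                    arm=str(row[arm]),
                    covariates={s.name: row[s.name] for s in specs},
                    observed_endpoint=None if pd.isna(endpoint) else float(endpoint),
                )
            )
        dataset = TrialDataset(
            records=records,
            arms=tuple(arms),
            specs=list(specs),
            outcome_transform=transform,
            better_direction=better_direction,
            outcome_name=outcome,
        )
        return cls(dataset)

    def fit(self, centering: str = "full") -> "PAIResults":
        """Run the leave-one-out prediction pipeline and a full-sample fit.

        Parameters
        ----------
        centering : {"full", "per_fold"}
            Whether "auto" centering constants come from the full sample
            (once) or are recomputed inside each training fold.
        """
        predictions = loo_predict(self.dataset, centering=centering)
        full_fit = fit_full_sample(self.dataset)
        return PAIResults(self, predictions, full_fit, centering)

    def baseline_balance(self, welch: bool = False):
        """Arm-balance tests for every declared covariate."""
        return baseline_balance(self.dataset, welch=welch)


class PAIResults:
    """Results of a fitted :class:`PAIModel`.

    Attributes
    ----------
    predictions : list of PatientPrediction
        One entry per patient, with factual/counterfactual predicted
        endpoints (outcome units), PAI and Optimal-arm label.
    full_sample_fit : ModelFit
        Coefficients of the all-patients fit (transformed scale), for
        reporting; the per-patient predictions never use it.
    """

    def __init__(
        self,
        model: PAIModel,
        predictions: list[PatientPrediction],
        full_sample_fit: ModelFit,
        centering: str,
    ):
        self.model = model
        self.predictions = predictions
        self.full_sample_fit = full_sample_fit
        self.centering = centering

    @property
    def dataset(self) -> TrialDataset:
        return self.model.dataset

    def predictions_frame(self) -> pd.DataFrame:
        from .io import predictions_to_frame

        return predictions_to_frame(self.predictions, self.dataset.arms)

    @property
    def pai_values(self) -> np.ndarray:
        return np.array([p.pai for p in self.predictions])

    def evaluate(self, threshold: float = 3.0, welch: bool = False) -> EvaluationSummary:
        """Error metrics, PAI distribution, Optimal/Non-optimal comparison."""
        return evaluate_predictions(self.predictions, threshold=threshold, welch=welch)

    def report(self, threshold: float = 3.0, metadata: Optional[dict] = None) -> dict:
        """Machine-readable report bundle (summary + histogram data)."""
        return build_report(
            self.predictions, self.evaluate(threshold=threshold), metadata=metadata
        )

    def residual_normality(self) -> tuple[float, float, str]:
        """Shapiro-Wilk check of full-sample residuals on the model scale."""
        from .engine import build_design_row
        from .preprocessing import resolve_centers

        ds = self.dataset
        records = list(ds.records)
        raw_cols = {
            s.name: np.array([float(r.covariates[s.name]) for r in records])
            for s in ds.specs
            if s.kind in ("continuous", "capped_count")
        }
        centers = resolve_centers(ds.specs, raw_cols)
        resid = []
        for rec in records:
            row = build_design_row(rec, ds, rec.arm, centers)
            z_hat = self.full_sample_fit.predict_row(row)
            z_obs = transform_outcome(rec.observed_endpoint, ds.outcome_transform)
            resid.append(z_obs - z_hat)
        return residual_normality_check(resid)

    def summary(self, threshold: float = 3.0) -> str:
        """Plain-text summary: coefficients, error metrics, group comparison."""
        ds = self.dataset
        ev = self.evaluate(threshold=threshold)
        lines = []
        lines.append("Personalized Advantage Index results")
        lines.append("=" * 60)
        lines.append(
            f"n = {ds.n} patients; arms: {ds.arms[0]} (+1/2, "
            f"n={sum(r.arm == ds.arms[0] for r in ds.records)}) vs "
            f"{ds.arms[1]} (-1/2, "
            f"n={sum(r.arm == ds.arms[1] for r in ds.records)})"
        )
        lines.append(
            f"outcome: {ds.outcome_name} ({ds.outcome_transform} scale, "
            f"{ds.better_direction} is better); LOO centering: {self.centering}"
        )
        lines.append("-" * 60)
        lines.append(f"{'term':<36}{'coef (full sample)':>20}")
        for term, beta in self.full_sample_fit.coefficients.items():
            lines.append(f"{term:<36}{beta:>20.4f}")
        lines.append(
            f"{'residual sd (transformed scale)':<36}"
            f"{self.full_sample_fit.residual_sd:>20.4f}"
        )
        lines.append("-" * 60)
        lines.append(f"true error (MAE):        {ev.true_error:8.2f}")
        lines.append(f"SE of prediction (RMSE): {ev.se_prediction:8.2f}")
        lines.append(f"mean PAI (SD):           {ev.mean_pai:8.2f} ({ev.sd_pai:.2f})")
        lines.append(
            f"PAI >= {threshold:g}:              "
            f"{ev.n_above_threshold:4d} of {ev.n}"
        )
        fs = ev.full_sample
        lines.append(
            f"Optimal vs Non-optimal (full sample): diff = {fs.mean_diff:.2f}, "
            f"d = {fs.cohens_d:.2f} [{fs.d_ci_low:.2f}, {fs.d_ci_high:.2f}], "
            f"t({fs.df}) = {fs.t_stat:.2f}, p = {fs.p_value:.3f}"
        )
        if ev.significant_subsample is not None:
            ss = ev.significant_subsample
            lines.append(
                f"Optimal vs Non-optimal (PAI >= {threshold:g}):  "
                f"diff = {ss.mean_diff:.2f}, "
                f"d = {ss.cohens_d:.2f} [{ss.d_ci_low:.2f}, {ss.d_ci_high:.2f}], "
                f"t({ss.df}) = {ss.t_stat:.2f}, p = {ss.p_value:.3f}"
            )
        for note in ev.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def plot_pai_hist(self, ax=None, bin_width: float = 1.0):
        """Histogram of PAI values (advantage of the Optimal arm)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.pai_values
        top = max(float(np.ceil(vals.max() / bin_width)) * bin_width, bin_width)
        ax.hist(vals, bins=np.arange(0.0, top + bin_width / 2, bin_width),
                edgecolor="black")
        ax.set_xlabel("PAI (outcome points)")
        ax.set_ylabel("patients")
        return ax

    def plot_predicted_hist(self, ax=None, bin_width: float = 1.0):
        """Histograms of predicted endpoints under Optimal / Non-optimal arm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        opt, non = [], []
        for p in self.predictions:
            if p.optimal_arm == "none":
                continue
            other = [a for a in p.pred_by_arm if a != p.optimal_arm][0]
            opt.append(p.pred_by_arm[p.optimal_arm])
            non.append(p.pred_by_arm[other])
        top = max(max(opt + non), bin_width)
        bins = np.arange(0.0, np.ceil(top / bin_width) * bin_width + bin_width / 2,
                         bin_width)
        ax.hist(opt, bins=bins, alpha=0.6, label="Optimal arm")
        ax.hist(non, bins=bins, alpha=0.6, label="Non-optimal arm")
        ax.set_xlabel("predicted endpoint")
        ax.set_ylabel("patients")
        ax.legend()
        return ax
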