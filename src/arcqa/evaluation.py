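"""Regression/classification assessment, interpretability, workload model.

Residuals follow the convention ``measured - predicted``, so overestimated
low GPR values show up as negative residuals.  The precision-recall curve
uses step-interpolated average precision, the standard that makes the
always-positive baseline equal the fail prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import ModelBundle, apply_scaler

__all__ = [
    "ConfusionCounts", "WorkloadModel", "EvaluationReport",
    "regression_report", "classification_metrics", "confusion_at_threshold",
    "roc_pr_curves", "partial_dependence", "workload_reduction",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts at a given threshold; 'fail' is the positive class."""

    true_fail: int
    false_pass: int  # fails not flagged
    true_pass: int
    false_fail: int  # passes flagged as fail

    @property
    def total(self) -> int:
        return self.true_fail + self.false_pass + self.true_pass + self.false_fail


def confusion_at_threshold(predicted: np.ndarray, fail_labels: np.ndarray,
                           tl: float) -> ConfusionCounts:
    """Flag 'fail' when predicted GPR < tl; count against the truth."""
    flagged = np.asarray(predicted, dtype=float) < tl
    fail = np.asarray(fail_labels, dtype=bool)
    return ConfusionCounts(
        true_fail=int(np.sum(flagged & fail)),
        false_pass=int(np.sum(~flagged & fail)),
        true_pass=int(np.sum(~flagged & ~fail)),
        false_fail=int(np.sum(flagged & ~fail)),
    )


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and precision from confusion counts.

    A metric with zero denominator is reported as ``nan``.
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(counts.true_fail, counts.true_fail + counts.false_pass),
        "specificity": ratio(counts.true_pass, counts.true_pass + counts.false_fail),
        "precision": ratio(counts.true_fail, counts.true_fail + counts.false_fail),
    }


def regression_report(measured: np.ndarray, predicted: np.ndarray) -> dict:
    """MAE, R^2, residual quartiles and absolute-error statistics."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.size < 2:
        raise ValueError("need two same-length vectors of at least 2 points")
    residual = measured - predicted
    abs_err = np.abs(residual)
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: measured values have zero variance")
    r2 = 1.0 - float(np.sum(residual ** 2)) / ss_tot
    return {
        "mae": float(abs_err.mean()),
        "r2": r2,
        "residual_quartiles": [float(q) for q in
                               np.percentile(residual, [25, 50, 75])],
        "abs_err_percentiles": {str(p): float(np.percentile(abs_err, p))
                                for p in (75, 90, 95, 98)},
        "frac_within": {str(b): float(np.mean(abs_err <= b))
                        for b in (3.0, 5.0, 10.0)},
        "max_abs_residual": float(abs_err.max()),
    }


def roc_pr_curves(predicted: np.ndarray, fail_labels: np.ndarray) -> dict:
    """ROC and precision-recall curves from a threshold sweep.

    The score is the negated predicted GPR (lower prediction = more
    fail-like).  AUC uses the trapezoid rule; average precision uses step
    interpolation.  Baselines for a chance classifier and an
    always-positive classifier are included.
    """
    predicted = np.asarray(predicted, dtype=float)
    fail = np.asarray(fail_labels, dtype=bool)
    n_pos = int(fail.sum())
    n_neg = int((~fail).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    score = -predicted
    order = np.argsort(-score, kind="mergesort")  # descending score
    sorted_fail = fail[order]
    sorted_score = score[order]
    tp = np.cumsum(sorted_fail)
    fp = np.cumsum(~sorted_fail)
    # collapse ties: keep the last entry of each distinct score
    distinct = np.concatenate([sorted_score[1:] != sorted_score[:-1], [True]])
    tp, fp = tp[distinct], fp[distinct]

    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))

    recall = tp / n_pos
    precision = tp / (tp + fp)
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - recall_prev) * precision))

    prevalence = n_pos / (n_pos + n_neg)
    return {
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "pr": {"recall": recall.tolist(), "precision": precision.tolist()},
        "auc": auc,
        "ap": ap,
        "baseline_auc": 0.5,
        "baseline_ap": float(prevalence),
        "prevalence": float(prevalence),
    }


def partial_dependence(bundle: ModelBundle, rows, feature: str,
                       n_grid: int = 20,
                       pct_range: tuple[float, float] = (5.0, 95.0)) -> dict:
    """Partial dependence of the predicted GPR on one feature.

    For each grid value the feature column is overwritten in every row and
    the mean prediction recorded; the grid spans the requested percentile
    range of the observed values.
    """
    if feature not in bundle.features:
        raise ValueError(f"feature {feature!r} not in the model")
    lo, hi = np.percentile(rows[feature].to_numpy(dtype=float), pct_range)
    grid = np.linspace(lo, hi, n_grid)
    work = rows.copy()
    means = np.empty(n_grid)
    for i, g in enumerate(grid):
        work[feature] = g
        X = apply_scaler(bundle.scaler, work)
        means[i] = float(np.clip(bundle.forest.predict(X), 0, 100).mean())
    return {"feature": feature, "grid": grid.tolist(), "mean_prediction": means.tolist()}


@dataclass(frozen=True)
class WorkloadModel:
    """Triage workload model for virtual QA.

    Flagged arcs get a quick reoptimization (``t_reopt``); unflagged true
    failures surface at measurement and cost a full replanning cycle
    (``t_replan``).  The baseline workload handles every true failure with
    a full cycle.
    """

    prevalence: float  # fraction of failing arcs
    sensitivity: float
    specificity: float
    t_reopt: float = 10.0  # min
    t_replan: float = 60.0  # min

    def __post_init__(self):
        for name in ("prevalence", "sensitivity", "specificity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.t_reopt <= 0 or self.t_replan <= 0:
            raise ValueError("times must be positive")


def workload_reduction(model: WorkloadModel) -> float:
    """Expected workload reduction (%) relative to measurement-only QA.

    Negative values mean the virtual-QA triage adds workload.
    """
    p, se, sp = model.prevalence, model.sensitivity, model.specificity
    if p <= 0:
        raise ValueError("prevalence must be positive")
    flagged = p * se + (1.0 - p) * (1.0 - sp)
    missed = p * (1.0 - se)
    triage = model.t_reopt * flagged + model.t_replan * missed
    baseline = model.t_replan * p
    return 100.0 * (1.0 - triage / baseline)


@dataclass
class EvaluationReport:
    """Full assessment of a trained model on a labelled partition."""

    regression: dict
    curves: dict
    at_tl: dict
    tl: float
    action_limit: float
    pdp: dict[str, dict] = field(default_factory=dict)
    workload: dict | None = None


def evaluate_model(bundle: ModelBundle, rows, measured: np.ndarray,
                   action_limit: float = 95.0, tl: float | None = None,
                   pdp_features: tuple[str, ...] = (),
                   workload_times: tuple[float, float] = (10.0, 60.0)
                   ) -> EvaluationReport:
    """Assess regression, classification and workload impact in one pass."""
    from .pipeline import predict_gpr

    measured = np.asarray(measured, dtype=float)
    predicted = predict_gpr(bundle, rows)
    fail = measured < action_limit
    tl = tl if tl is not None else (bundle.threshold_limit or action_limit)

    regression = regression_report(measured, predicted)
    curves = roc_pr_curves(predicted, fail)
    counts = confusion_at_threshold(predicted, fail, tl)
    at_tl = classification_metrics(counts)
    at_tl["counts"] = counts.__dict__

    workload = None
    prevalence = float(fail.mean())
    if 0 < prevalence < 1 and not np.isnan(at_tl["sensitivity"]):
        wm = WorkloadModel(prevalence=prevalence,
                           sensitivity=at_tl["sensitivity"],
                           specificity=at_tl["specificity"],
                           t_reopt=workload_times[0],
                           t_replan=workload_times[1])
        workload = {"model": wm.__dict__, "reduction_pct": workload_reduction(wm)}

    pdp = {f: partial_dependence(bundle, rows, f) for f in pdp_features}
    return EvaluationReport(regression=regression, curves=curves, at_tl=at_tl,
                            tl=float(tl), action_limit=action_limit, pdp=pdp,
                            workload=workload)
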