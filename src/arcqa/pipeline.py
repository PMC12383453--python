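"""Model-selection pipeline: hybrid split, weighting, scaling, search, calibration.

The data flow mirrors a prospective deployment: the most recent 20% of
arcs form the test set; the remaining (older) arcs are split into training
and validation sets stratified on the measured GPR.  Sample weights
emphasize low-GPR arcs, features are robust-scaled with percentile
statistics fitted per partition (and per CV fold, to avoid leakage), and a
randomized search over random-forest hyperparameters minimizes
cross-validated MAE.  A threshold limit (TL) on the predicted GPR is then
calibrated on the validation set for fail flagging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "DataSplit", "ScalerStats", "ModelBundle", "SearchResult", "ThresholdResult",
    "hybrid_split", "sample_weights", "fit_scaler", "apply_scaler",
    "default_search_space", "randomized_search", "train_model", "predict_gpr",
    "calibrate_threshold", "save_bundle", "load_bundle",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DataSplit:
    """Row positions (into the input table) of the three partitions."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    test_frac: float
    val_frac: float
    n_bins: int
    seed: int

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = len(self.train) + len(self.validation) + len(self.test)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions overlap")


def hybrid_split(table: pd.DataFrame, test_frac: float = 0.2,
                 val_frac: float = 0.2, n_bins: int = 10,
                 seed: int = 0, date_col: str = "treatment_date",
                 gpr_col: str = "measured_gpr", id_col: str = "arc_id"
                 ) -> DataSplit:
    """Time-series test split followed by GPR-stratified train/validation.

    Rows are ordered by date (ties broken by arc id); the newest
    ``round(test_frac * N)`` rows become the test set.  The remainder is
    binned into GPR deciles (bins merged until each holds at least 2 rows)
    and ``round(val_frac * remainder)`` rows are drawn proportionally from
    the bins into the validation set.
    """
    if date_col not in table.columns:
        raise ValueError(f"missing date column {date_col!r}")
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    order = table.reset_index(drop=True).sort_values(
        [date_col, id_col] if id_col in table.columns else [date_col],
        kind="mergesort").index.to_numpy()
    n_test = _round_half_up(test_frac * n)
    test_idx = order[n - n_test:]
    remainder = order[: n - n_test]

    gpr = table[gpr_col].to_numpy()[remainder]
    n_val = _round_half_up(val_frac * len(remainder))

    # decile bins of the remainder's GPR, merged until every bin has >= 2 rows
    edges = np.unique(np.percentile(gpr, np.linspace(0, 100, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, gpr, side="right") - 1, 0, len(edges) - 2)
    bins = _merge_small_bins(bins, min_size=2)

    rng = np.random.default_rng(seed)
    val_mask = np.zeros(len(remainder), dtype=bool)
    uniq, counts = np.unique(bins, return_counts=True)
    quotas = counts * n_val / len(remainder)
    base = np.floor(quotas).astype(int)
    short = n_val - base.sum()
    if short > 0:  # largest-remainder allocation
        extra = np.argsort(-(quotas - base), kind="mergesort")[:short]
        base[extra] += 1
    for b, take in zip(uniq, base):
        members = np.where(bins == b)[0]
        chosen = rng.choice(members, size=min(take, len(members)), replace=False)
        val_mask[chosen] = True
    return DataSplit(train=remainder[~val_mask], validation=remainder[val_mask],
                     test=test_idx, test_frac=test_frac, val_frac=val_frac,
                     n_bins=n_bins, seed=seed)


def _merge_small_bins(bins: np.ndarray, min_size: int) -> np.ndarray:
    """Merge adjacent bins (by label order) until all have >= min_size rows."""
    bins = bins.copy()
    while True:
        uniq, counts = np.unique(bins, return_counts=True)
        if len(uniq) <= 1 or counts.min() >= min_size:
            return bins
        k = int(np.argmin(counts))
        target = uniq[k - 1] if k > 0 else uniq[k + 1]
        bins[bins == uniq[k]] = target


def sample_weights(gpr: np.ndarray, scale: float = 1.0,
                   offset: float = 0.1) -> np.ndarray:
    """Per-instance weights ``10 ** (scale * (offset - GPR))``.

    GPR values are fractions in [0, 1]; the defaults give the literal
    ``10 ** (0.1 - GPR)`` weighting that prioritizes low-GPR arcs.
    """
    gpr = np.asarray(gpr, dtype=float)
    if np.any((gpr < 0) | (gpr > 1)):
        raise ValueError("GPR values must be fractions in [0, 1]")
    return 10.0 ** (scale * (offset - gpr))


@dataclass
class ScalerStats:
    """Percentile statistics of the fitting partition, per feature."""

    q25: pd.Series
    q50: pd.Series
    q75: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.q50.index)


def fit_scaler(rows: pd.DataFrame, features: list[str]) -> ScalerStats:
    """Fit 25/50/75th percentile statistics on the given partition."""
    if len(rows) < 4:
        raise ValueError("need at least 4 rows to fit the scaler")
    q = rows[features].quantile([0.25, 0.50, 0.75])
    return ScalerStats(q25=q.loc[0.25], q50=q.loc[0.50], q75=q.loc[0.75])


def apply_scaler(stats: ScalerStats, rows: pd.DataFrame) -> pd.DataFrame:
    """Robust-scale features: ``(f - f50%) / (f75% - f25%)``.

    Features with zero IQR in the fitting partition map to 0 (a warning is
    emitted once per call).
    """
    iqr = stats.q75 - stats.q25
    zero = iqr[iqr == 0].index.tolist()
    if zero:
        warnings.warn(f"zero IQR for features {zero}; scaled values set to 0",
                      stacklevel=2)
    out = (rows[stats.features] - stats.q50) / iqr.replace(0.0, np.nan)
    return out.fillna(0.0)


_MAX_FEATURES_OPTIONS = ["sqrt", "log2", 0.3, 0.5, 0.7, 1.0]


def default_search_space() -> dict[str, Callable[[np.random.Generator], object]]:
    """The committed hyperparameter space for the randomized search."""
    return {
        "n_estimators": lambda rng: int(rng.integers(100, 1001)),
        "max_depth": lambda rng: (None if rng.random() < 0.25
                                  else int(rng.integers(5, 31))),
        "min_samples_leaf": lambda rng: int(rng.integers(1, 21)),
        "min_samples_split": lambda rng: int(rng.integers(2, 21)),
        "max_features": lambda rng: _MAX_FEATURES_OPTIONS[
            int(rng.integers(len(_MAX_FEATURES_OPTIONS)))],
    }


@dataclass
class SearchResult:
    best_params: dict
    cv_mae_mean: float
    cv_mae_std: float
    n_iter: int
    seed: int
    history: list[dict] = field(default_factory=list)


def randomized_search(train: pd.DataFrame, features: list[str],
                      space: dict | None = None, n_iter: int = 1000,
                      k_folds: int = 5, seed: int = 0,
                      gpr_col: str = "measured_gpr",
                      weight_scale: float = 1.0,
                      audit: list | None = None) -> SearchResult:
    """Randomized hyperparameter search with leakage-safe cross-validation.

    Every fold fits its own scaler statistics on the fold's training rows
    only.  The score is the unweighted MAE (percent GPR) averaged over
    folds; fitting uses the low-GPR-emphasizing sample weights.  Pass an
    ``audit`` list to capture per-fold scaler statistics and row indices
    (used by the no-leakage tests).
    """
    if len(train) < 50:
        raise ValueError("need at least 50 training rows for the search")
    if space is None:
        space = default_search_space()
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    train = train.reset_index(drop=True)
    y = train[gpr_col].to_numpy(dtype=float)

    folds = list(KFold(n_splits=k_folds, shuffle=True,
                       random_state=seed).split(train))
    best: tuple[float, float, dict] | None = None
    history = []
    for it in range(n_iter):
        params = {name: draw(rng) for name, draw in space.items()}
        maes = []
        for fold_id, (tr, va) in enumerate(folds):
            stats = fit_scaler(train.iloc[tr], features)
            if audit is not None:
                audit.append({"iteration": it, "fold": fold_id,
                              "train_rows": tr.copy(), "val_rows": va.copy(),
                              "stats": stats})
            Xtr = apply_scaler(stats, train.iloc[tr])
            Xva = apply_scaler(stats, train.iloc[va])
            w = sample_weights(y[tr] / 100.0, scale=weight_scale)
            forest = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
            forest.fit(Xtr, y[tr], sample_weight=w)
            pred = np.clip(forest.predict(Xva), 0.0, 100.0)
            maes.append(float(np.mean(np.abs(pred - y[va]))))
        mean_mae, std_mae = float(np.mean(maes)), float(np.std(maes))
        history.append({"params": params, "cv_mae_mean": mean_mae,
                        "cv_mae_std": std_mae})
        if best is None or mean_mae < best[0]:
            best = (mean_mae, std_mae, params)
    return SearchResult(best_params=best[2], cv_mae_mean=best[0],
                        cv_mae_std=best[1], n_iter=n_iter, seed=seed,
                        history=history)


@dataclass
class ModelBundle:
    """Everything needed to score new arcs."""

    features: list[str]
    scaler: ScalerStats
    forest: RandomForestRegressor
    params: dict
    seed: int
    threshold_limit: float | None = None  # TL on predicted GPR, percent
    version: str = "1"


def train_model(train: pd.DataFrame, features: list[str], params: dict,
                seed: int = 0, gpr_col: str = "measured_gpr",
                weight_scale: float = 1.0) -> ModelBundle:
    """Refit the forest on the full training partition."""
    stats = fit_scaler(train, features)
    X = apply_scaler(stats, train)
    y = train[gpr_col].to_numpy(dtype=float)
    w = sample_weights(y / 100.0, scale=weight_scale)
    forest = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    forest.fit(X, y, sample_weight=w)
    return ModelBundle(features=list(features), scaler=stats, forest=forest,
                       params=dict(params), seed=seed)


def predict_gpr(bundle: ModelBundle, rows: pd.DataFrame) -> np.ndarray:
    """Predicted GPR (%) clipped to [0, 100]."""
    missing = [f for f in bundle.features if f not in rows.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = apply_scaler(bundle.scaler, rows)
    return np.clip(bundle.forest.predict(X), 0.0, 100.0)


@dataclass
class ThresholdResult:
    tl: float  # percent, flag "fail" when predicted GPR < tl
    sensitivity: float
    specificity: float
    feasible: bool


def calibrate_threshold(predicted: np.ndarray, fail_labels: np.ndarray,
                        sens_min: float = 0.90, spec_min: float = 0.50
                        ) -> ThresholdResult:
    """Choose the TL on predicted GPR meeting sensitivity/specificity floors.

    Candidates are the distinct predicted values and their midpoints.
    Among candidates with sensitivity >= sens_min and specificity >=
    spec_min the one maximizing specificity is returned (ties -> lower
    TL).  If no candidate satisfies both floors, the result maximizes
    specificity subject to the sensitivity floor alone and is flagged
    infeasible.
    """
    predicted = np.asarray(predicted, dtype=float)
    fail = np.asarray(fail_labels, dtype=bool)
    if fail.all() or not fail.any():
        raise ValueError("validation set must contain both classes")

    vals = np.unique(predicted)
    mids = (vals[:-1] + vals[1:]) / 2.0
    candidates = np.unique(np.concatenate([vals, mids, [vals[-1] + 1e-6]]))

    best_ok = None
    best_sens_only = None
    for tl in candidates:
        flagged = predicted < tl
        sens = float(np.mean(flagged[fail]))
        spec = float(np.mean(~flagged[~fail]))
        entry = (spec, -tl, tl, sens)
        if sens >= sens_min:
            if best_sens_only is None or entry > best_sens_only:
                best_sens_only = entry
            if spec >= spec_min and (best_ok is None or entry > best_ok):
                best_ok = entry
    chosen = best_ok if best_ok is not None else best_sens_only
    feasible = best_ok is not None
    spec, _, tl, sens = chosen
    return ThresholdResult(tl=float(tl), sensitivity=sens, specificity=spec,
                           feasible=feasible)


def save_bundle(bundle: ModelBundle, path) -> None:
    joblib.dump(bundle, path)


def load_bundle(path) -> ModelBundle:
    bundle = joblib.load(path)
    if not isinstance(bundle, ModelBundle):
        raise TypeError("file does not contain a model bundle")
    return bundle
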