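"""Tree-ensemble yield regression and balance classification.

Two supervised stages over the trial feature matrix:

- **Regression** of marketable bulb yield (kg/ha) with a random forest
  (10 trees per bag) or extreme gradient boosting (100 trees), evaluated by
  repeated stratified 70:30 train/test partitions; RMSE, MAE and R² are
  averaged over repeats.
- **Classification** of specimens at a yield cutoff (50 Mg/ha) from cultivar
  and tissue features.  Out-of-fold predictions across repeats assign each
  specimen to a confusion quadrant: a *true negative* yields above the
  cutoff with a composition classified as balanced — the reference
  population for tissue nutrient standards.  (Positive = predicted
  nutritionally imbalanced, i.e. predicted below-cutoff.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier, XGBRegressor

from .compositions import NUTRIENTS, Composition, close_composition
from .feature_table import FeatureMatrix, TrialObservation, stratified_split

QUADRANTS = ("TN", "FN", "FP", "TP")


class DegenerateLabelsError(ValueError):
    """Only one class present at the chosen yield cutoff."""


@dataclass(frozen=True)
class ModelConfig:
    """Learner and evaluation-protocol settings."""

    learner: str = "random_forest"      # "random_forest" | "gradient_boosting"
    trees_per_bag: int = 10             # random forest
    boosting_trees: int = 100           # gradient boosting
    max_depth: int = 6                  # gradient boosting
    learning_rate: float = 0.3          # gradient boosting
    train_fraction: float = 0.70
    repeats: int = 100
    yield_cutoff_mg_ha: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in ("random_forest", "gradient_boosting"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if min(self.trees_per_bag, self.boosting_trees) < 1:
            raise ValueError("tree counts must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def yield_cutoff_kg_ha(self) -> float:
        return self.yield_cutoff_mg_ha * 1000.0


def _repeat_seeds(config: ModelConfig) -> np.ndarray:
    """Deterministic (split, model) seed pairs, one per repeat."""
    state = np.random.SeedSequence(int(config.seed) % (2**31)).generate_state(2 * config.repeats)
    return (state % (2**31)).reshape(config.repeats, 2)


def _make_regressor(config: ModelConfig, seed: int):
    if config.learner == "random_forest":
        return RandomForestRegressor(
            n_estimators=config.trees_per_bag, random_state=int(seed), n_jobs=1
        )
    return XGBRegressor(
        n_estimators=config.boosting_trees,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        random_state=int(seed),
        n_jobs=1,
        verbosity=0,
        tree_method="hist",
    )


def _make_classifier(config: ModelConfig, seed: int):
    if config.learner == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.trees_per_bag, random_state=int(seed), n_jobs=1
        )
    return XGBClassifier(
        n_estimators=config.boosting_trees,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        random_state=int(seed),
        n_jobs=1,
        verbosity=0,
        tree_method="hist",
        eval_metric="logloss",
    )


@dataclass
class RegressionReport:
    """Averaged and per-repeat accuracy of the yield regression."""

    rmse: float
    mae: float
    median_ae: float
    r2: float
    per_repeat: pd.DataFrame
    predictions: pd.DataFrame   # columns: repeat, row, y_true, y_pred
    config: ModelConfig
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def write(self, path) -> None:
        self.per_repeat.to_csv(path, index=False)


@dataclass
class ClassificationReport:
    """Averaged AUC/CA and per-specimen confusion quadrants."""

    auc: float
    ca: float
    cutoff_mg_ha: float
    per_repeat: pd.DataFrame
    quadrants: pd.Series        # one of TN/FN/FP/TP per specimen
    actual_high: np.ndarray
    predicted_high: np.ndarray
    votes: pd.DataFrame         # columns: row, n_test, n_predicted_high
    config: ModelConfig
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def quadrant_counts(self) -> dict[str, int]:
        return {q: int((self.quadrants == q).sum()) for q in QUADRANTS}

    def write(self, path) -> None:
        self.per_repeat.to_csv(path, index=False)


def evaluate_regression(matrix: FeatureMatrix, config: ModelConfig) -> RegressionReport:
    """Repeated stratified hold-out evaluation of the yield regression.

    For each repeat: a stratified ``train_fraction`` split, a fresh ensemble
    fit on the training fold, and RMSE / mean-AE / median-AE / R² on the
    test fold.  R² is ``1 - SSE/SST`` on the test fold.  Reported metrics
    are means over repeats; the report also carries the per-repeat values,
    every out-of-fold prediction and the split memberships for audit.
    """
    if matrix.has_missing():
        raise ValueError("regression requires a complete (imputed) matrix")
    y = matrix.target.to_numpy(dtype=float)
    X = matrix.X.to_numpy(dtype=float)
    rows_metrics, rows_pred, splits = [], [], []
    for repeat, (split_seed, model_seed) in enumerate(_repeat_seeds(config)):
        train, test = stratified_split(matrix, config.train_fraction, seed=int(split_seed))
        if test.size == 0:
            raise ValueError("empty test fold; check strata and train_fraction")
        model = _make_regressor(config, model_seed)
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[test]), dtype=float)
        resid = y[test] - pred
        sst = float(np.sum((y[test] - y[test].mean()) ** 2))
        rows_metrics.append(
            {
                "repeat": repeat,
                "rmse": float(np.sqrt(np.mean(resid**2))),
                "mae": float(np.mean(np.abs(resid))),
                "median_ae": float(np.median(np.abs(resid))),
                "r2": 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan,
            }
        )
        rows_pred.extend(
            {"repeat": repeat, "row": int(r), "y_true": float(y[r]), "y_pred": float(p)}
            for r, p in zip(test, pred)
        )
        splits.append((train, test))
    per_repeat = pd.DataFrame(rows_metrics)
    return RegressionReport(
        rmse=float(per_repeat["rmse"].mean()),
        mae=float(per_repeat["mae"].mean()),
        median_ae=float(per_repeat["median_ae"].mean()),
        r2=float(per_repeat["r2"].mean()),
        per_repeat=per_repeat,
        predictions=pd.DataFrame(rows_pred),
        config=config,
        splits=splits,
    )


def classify_balance(matrix: FeatureMatrix, config: ModelConfig) -> ClassificationReport:
    """Classify specimens at the yield cutoff and assign confusion quadrants.

    The class label is ``yield > cutoff`` (high-yield, equivalently
    *nutritionally balanced* when predicted from cultivar + tissue).  The
    split protocol mirrors the regression; AUC and classification accuracy
    are averaged over repeats.  Each specimen's quadrant comes from the
    majority vote of its out-of-fold predictions (ties count as predicted
    balanced); specimens that never reach a test fold fall back to an
    in-sample prediction with a warning.
    """
    if matrix.has_missing():
        raise ValueError("classification requires a complete (imputed) matrix")
    y_kg = matrix.target.to_numpy(dtype=float)
    actual_high = y_kg > config.yield_cutoff_kg_ha
    if actual_high.all() or not actual_high.any():
        raise DegenerateLabelsError(
            f"all specimens on one side of the {config.yield_cutoff_mg_ha} Mg/ha cutoff"
        )
    X = matrix.X.to_numpy(dtype=float)
    n = len(y_kg)
    n_test = np.zeros(n, dtype=int)
    n_pred_high = np.zeros(n, dtype=int)
    rows_metrics, splits = [], []
    for repeat, (split_seed, model_seed) in enumerate(_repeat_seeds(config)):
        train, test = stratified_split(matrix, config.train_fraction, seed=int(split_seed))
        model = _make_classifier(config, model_seed)
        model.fit(X[train], actual_high[train])
        pred = np.asarray(model.predict(X[test])).astype(bool)
        classes = list(model.classes_)
        if True in classes and len(classes) == 2:
            proba = model.predict_proba(X[test])[:, classes.index(True)]
            auc = (
                roc_auc_score(actual_high[test], proba)
                if len(np.unique(actual_high[test])) == 2
                else np.nan
            )
        else:  # training fold degenerate; predict_proba has one column
            auc = np.nan
        rows_metrics.append(
            {
                "repeat": repeat,
                "auc": auc,
                "ca": float(np.mean(pred == actual_high[test])),
            }
        )
        n_test[test] += 1
        n_pred_high[test] += pred.astype(int)
        splits.append((train, test))

    never_tested = np.flatnonzero(n_test == 0)
    predicted_high = np.zeros(n, dtype=bool)
    tested = n_test > 0
    predicted_high[tested] = 2 * n_pred_high[tested] >= n_test[tested]
    if never_tested.size:
        warnings.warn(
            f"{never_tested.size} specimens never reached a test fold; "
            "using in-sample predictions for their quadrants",
            UserWarning,
            stacklevel=2,
        )
        fallback = _make_classifier(config, int(_repeat_seeds(config)[-1, 1]))
        fallback.fit(X, actual_high)
        predicted_high[never_tested] = (
            np.asarray(fallback.predict(X[never_tested])).astype(bool)
        )

    quadrant = np.where(
        actual_high,
        np.where(predicted_high, "TN", "FP"),
        np.where(predicted_high, "FN", "TP"),
    )
    per_repeat = pd.DataFrame(rows_metrics)
    return ClassificationReport(
        auc=float(per_repeat["auc"].mean(skipna=True)),
        ca=float(per_repeat["ca"].mean()),
        cutoff_mg_ha=config.yield_cutoff_mg_ha,
        per_repeat=per_repeat,
        quadrants=pd.Series(quadrant, name="quadrant"),
        actual_high=actual_high,
        predicted_high=predicted_high,
        votes=pd.DataFrame({"row": np.arange(n), "n_test": n_test, "n_predicted_high": n_pred_high}),
        config=config,
        splits=splits,
    )


def select_true_negatives(
    report: ClassificationReport,
    observations: Sequence[TrialObservation],
) -> list[tuple[int, str, Composition]]:
    """True-negative specimens (high yield, classified balanced) with tissue.

    Returns ``(row, cultivar, Composition)`` triples ready for standards
    derivation.  Rows with incomplete or non-positive tissue records are
    skipped with a warning; an empty selection warns that standards are
    impossible.
    """
    tn_rows = np.flatnonzero((report.quadrants == "TN").to_numpy())
    selected: list[tuple[int, str, Composition]] = []
    skipped = 0
    for row in tn_rows:
        obs = observations[row]
        tissue = obs.tissue_dict()
        values = [tissue[p] for p in NUTRIENTS]
        if not all(np.isfinite(v) and v > 0 for v in values):
            skipped += 1
            continue
        selected.append((int(row), obs.cultivar, close_composition(tissue)))
    if skipped:
        warnings.warn(f"skipped {skipped} TN specimens with incomplete tissue records",
                      UserWarning, stacklevel=2)
    if not selected:
        warnings.warn("no true-negative specimens selected; standards cannot be derived",
                      UserWarning, stacklevel=2)
    return selected
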