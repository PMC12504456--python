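"""Presence-absence classifiers: tuning, evaluation and interpretation.

Three learners are compared per genus — stochastic gradient boosting (GBM),
a support vector machine with radial basis function kernel (SVM) and a
random forest (RF) — around a shared protocol:

* stratified 75/25 train/test partition,
* hyperparameter tuning by mean AUC over a ten-fold cross-validation
  repeated ten times (fold assignment shared across the grid),
* GBM keeps shrinkage 0.1 and the minimum terminal-node size 20 fixed and
  tunes the number of trees and interaction depth; RF tunes the number of
  candidate variables per split (mtry); SVM tunes the kernel width (sigma,
  seeded by the median heuristic) and cost C,
* the final model is refit on all training rows at the AUC-maximising grid
  point; held-out class probabilities of every resample are retained (they
  later drive probability-threshold selection),
* test-set confusion matrices are formed at probability 0.5, and the
  cross-validation AUC standard deviation is the sample SD over the
  100 resample AUCs.

The learners themselves come from scikit-learn; everything around them
(resampling, tuning, metric formulas, importance scaling, partial
dependence) is implemented here. Predictors are centred/scaled for the SVM
only; the scaler is part of the model bundle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ConfusionMatrix", "MetricSet", "TrainedModel",
    "partition", "train_tuned", "metrics", "auc", "importance",
    "partial_dependence", "evaluate", "default_grid",
]


# ---------------------------------------------------------------------------
# confusion matrices and metric formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionMatrix":
        y = np.asarray(labels, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        return cls(
            tp=int(np.sum(y & p)), fp=int(np.sum(~y & p)),
            tn=int(np.sum(~y & ~p)), fn=int(np.sum(y & ~p)),
        )


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    auc: float = float("nan")
    auc_sd: float = float("nan")


def _ratio(num: float, den: float) -> float:
    # a zero denominator makes the metric undefined (NaN), not zero
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, precision, F1 and accuracy of one matrix."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    f1 = _ratio(2.0 * prec * sens, prec + sens) \
        if not (np.isnan(prec) or np.isnan(sens)) else float("nan")
    acc = _ratio(cm.tp + cm.tn, cm.total)
    return MetricSet(sens, spec, prec, f1, acc)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction.

    Undefined (NaN) when one class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# partitioning and resampling
# ---------------------------------------------------------------------------

def partition(n: int, labels, train_frac: float = 0.75, seed: int = 0,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; returns (train_idx, test_idx).

    Per class, ``ceil(train_frac * n_class)`` rows go to training, so class
    proportions in both splits stay within one observation of the overall
    proportion (e.g. 358 rows with 143 positives -> 270 train / 88 test).
    """
    y = np.asarray(labels, dtype=bool)
    if len(y) != n:
        raise ValueError("labels length mismatch")
    if y.all() or not y.any():
        raise ValueError("stratified split requires both classes")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = int(np.ceil(train_frac * len(idx)))
        train_parts.append(idx[:k])
        test_parts.append(idx[k:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def _cv_folds(y: np.ndarray, n_folds: int, n_repeats: int, seed: int):
    """(repeat, fold, train_idx, test_idx) tuples; folds with a single-class
    training side are regenerated under a fresh sub-seed."""
    ss = np.random.SeedSequence(seed)
    out = []
    for rep, rep_ss in enumerate(ss.spawn(n_repeats)):
        attempt_seed = rep_ss.generate_state(1)[0] % (2**31)
        for _ in range(20):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(attempt_seed))
            folds = list(skf.split(np.zeros_like(y), y))
            ok = all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
                     for tr, te in folds)
            if ok:
                break
            warnings.warn("degenerate fold encountered; regenerating", stacklevel=2)
            attempt_seed = (attempt_seed + 1) % (2**31)
        for f, (tr, te) in enumerate(folds):
            out.append((rep, f, tr, te))
    return out


# ---------------------------------------------------------------------------
# tuning grids
# ---------------------------------------------------------------------------

def _sigma_grid(X: np.ndarray) -> list[float]:
    """Median-heuristic band for the RBF width, kernlab-style.

    Quantiles (0.9, 0.5, 0.1) of pairwise squared distances between scaled
    rows give a low / central / high sigma where K = exp(-sigma * ||x-y||^2).
    """
    rng = np.random.default_rng(0)
    m = min(len(X), 200)
    sub = X[rng.choice(len(X), size=m, replace=False)]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    d2 = d2[np.triu_indices(m, 1)]
    qs = np.quantile(d2[d2 > 0], [0.9, 0.5, 0.1])
    return [float(1.0 / (2.0 * q)) for q in qs]


def default_grid(learner: str, n_features: int | None = None,
                 X: np.ndarray | None = None) -> dict:
    """Default hyperparameter grid per learner (config-overridable)."""
    if learner == "gbm":
        return {"n_trees": list(range(50, 501, 50)),
                "interaction_depth": [1, 2, 3]}
    if learner == "rf":
        p = n_features or 2
        mtry = np.unique(np.linspace(1, p, num=min(p, 5)).round().astype(int))
        return {"mtry": mtry.tolist()}
    if learner == "svm":
        if X is None:
            raise ValueError("SVM grid needs the training matrix for sigma")
        return {"sigma": _sigma_grid(X), "C": [0.25, 0.5, 1.0, 2.0, 4.0]}
    raise ValueError(f"unknown learner {learner!r}")


# GBM constants held fixed during tuning
GBM_SHRINKAGE = 0.1
GBM_MIN_NODE = 20
GBM_BAG_FRACTION = 0.5
RF_N_TREES = 500


# ---------------------------------------------------------------------------
# trained model bundle
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A tuned classifier plus its cross-validation records."""

    learner: str
    feature_names: list[str]
    best_params: dict
    cv_grid: pd.DataFrame        # one row per grid point with mean CV AUC
    cv_records: pd.DataFrame     # repeat, fold, auc, sensitivity, specificity
    cv_predictions: pd.DataFrame  # repeat, fold, row, prob, label (chosen point)
    cv_auc_mean: float
    cv_auc_sd: float
    model: object
    scaler: object | None = None
    X_train: pd.DataFrame | None = None
    y_train: np.ndarray | None = None

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        M = X[self.feature_names].to_numpy(float)
        if self.scaler is not None:
            M = self.scaler.transform(M)
        return M

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class probability per row."""
        return self.model.predict_proba(self._matrix(X))[:, 1]


def _make_estimator(learner: str, params: dict, seed: int):
    if learner == "gbm":
        return GradientBoostingClassifier(
            n_estimators=params["n_trees"],
            max_depth=params["interaction_depth"],
            learning_rate=GBM_SHRINKAGE,
            min_samples_leaf=GBM_MIN_NODE,
            subsample=GBM_BAG_FRACTION,
            random_state=seed,
        )
    if learner == "rf":
        return RandomForestClassifier(
            n_estimators=RF_N_TREES, max_features=params["mtry"],
            random_state=seed, n_jobs=1,
        )
    if learner == "svm":
        return SVC(
            C=params["C"], gamma=params["sigma"], kernel="rbf",
            probability=True, random_state=seed,
        )
    raise ValueError(f"unknown learner {learner!r}")


def _fold_stats(y_te, probs) -> tuple[float, float, float]:
    cm = ConfusionMatrix.from_predictions(y_te, probs >= 0.5)
    m = metrics(cm)
    return auc(probs, y_te), m.sensitivity, m.specificity


def train_tuned(X: pd.DataFrame, y, learner: str, grid: dict | None = None,
                n_folds: int = 10, n_repeats: int = 10, seed: int = 0,
                ) -> TrainedModel:
    """Tune a learner by repeated-CV mean AUC and refit on all rows.

    For the GBM the whole ``n_trees`` axis of the grid is scored from a
    single staged fit per (depth, resample), so the nominal grid costs only
    ``len(interaction_depth)`` fits per resample.
    """
    y = np.asarray(y, dtype=bool)
    if X.isna().to_numpy().any():
        raise ValueError("predictors contain missing values")
    feature_names = list(X.columns)
    M_raw = X.to_numpy(float)

    scaler = None
    M = M_raw
    if learner == "svm":
        scaler = StandardScaler().fit(M_raw)
        M = scaler.transform(M_raw)

    if grid is None:
        grid = default_grid(learner, n_features=M.shape[1], X=M)

    ss = np.random.SeedSequence(seed)
    fold_seed, fit_seed = (s.generate_state(1)[0] % (2**31) for s in ss.spawn(2))
    folds = _cv_folds(y, n_folds, n_repeats, int(fold_seed))

    # per grid point: held-out probabilities of every resample
    if learner == "gbm":
        points = [{"n_trees": t, "interaction_depth": d}
                  for d in grid["interaction_depth"] for t in grid["n_trees"]]
        probs_by_point: dict[int, list] = {i: [] for i in range(len(points))}
        tree_counts = list(grid["n_trees"])
        for rep, f, tr, te in folds:
            for d in grid["interaction_depth"]:
                est = GradientBoostingClassifier(
                    n_estimators=max(tree_counts),
                    max_depth=d, learning_rate=GBM_SHRINKAGE,
                    min_samples_leaf=GBM_MIN_NODE, subsample=GBM_BAG_FRACTION,
                    random_state=int(fit_seed),
                )
                est.fit(M[tr], y[tr])
                staged = list(est.staged_predict_proba(M[te]))
                for t in tree_counts:
                    i = points.index({"n_trees": t, "interaction_depth": d})
                    probs_by_point[i].append((rep, f, te, staged[t - 1][:, 1]))
    else:
        if learner == "rf":
            points = [{"mtry": m} for m in grid["mtry"]]
        else:
            points = [{"sigma": s, "C": c}
                      for s in grid["sigma"] for c in grid["C"]]
        probs_by_point = {i: [] for i in range(len(points))}
        for rep, f, tr, te in folds:
            for i, params in enumerate(points):
                est = _make_estimator(learner, params, int(fit_seed))
                est.fit(M[tr], y[tr])
                probs_by_point[i].append((rep, f, te, est.predict_proba(M[te])[:, 1]))

    grid_rows = []
    for i, params in enumerate(points):
        aucs = [auc(p, y[te]) for _, _, te, p in probs_by_point[i]]
        grid_rows.append({**params, "cv_auc": float(np.nanmean(aucs))})
    cv_grid = pd.DataFrame(grid_rows)
    best_i = int(cv_grid["cv_auc"].idxmax())
    best_params = points[best_i]

    rec_rows, pred_rows = [], []
    best_aucs = []
    for rep, f, te, p in probs_by_point[best_i]:
        a, se, sp = _fold_stats(y[te], p)
        best_aucs.append(a)
        rec_rows.append({"repeat": rep, "fold": f, "auc": a,
                         "sensitivity": se, "specificity": sp})
        for row, prob in zip(te, p):
            pred_rows.append({"repeat": rep, "fold": f, "row": int(row),
                              "prob": float(prob), "label": bool(y[row])})
    cv_records = pd.DataFrame(rec_rows)
    cv_predictions = pd.DataFrame(pred_rows)

    final = _make_estimator(learner, best_params, int(fit_seed))
    final.fit(M, y)

    best_aucs = np.asarray(best_aucs, dtype=float)
    return TrainedModel(
        learner=learner, feature_names=feature_names, best_params=best_params,
        cv_grid=cv_grid, cv_records=cv_records, cv_predictions=cv_predictions,
        cv_auc_mean=float(np.nanmean(best_aucs)),
        cv_auc_sd=float(np.nanstd(best_aucs, ddof=1)) if len(best_aucs) > 1 else 0.0,
        model=final, scaler=scaler,
        X_train=X.copy(), y_train=y.copy(),
    )


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def importance(model: TrainedModel) -> pd.DataFrame:
    """Per-variable importance, min-max scaled so the maximum is 100.

    GBM and RF expose their native (relative-influence / impurity)
    importances; for the SVM a model-free filter is used: each variable's
    standalone discriminatory AUC on the training data, folded around 0.5.
    """
    if model.learner in ("gbm", "rf"):
        raw = np.asarray(model.model.feature_importances_, dtype=float)
    else:
        y = model.y_train
        raw = np.array([
            max(a, 1.0 - a) for a in (
                auc(model.X_train[c].to_numpy(float), y)
                for c in model.feature_names)
        ])
    lo, hi = raw.min(), raw.max()
    scaled = np.full_like(raw, 100.0) if hi == lo else (raw - lo) / (hi - lo) * 100.0
    return (
        pd.DataFrame({"variable": model.feature_names, "importance": scaled})
        .sort_values("importance", ascending=False, ignore_index=True)
    )


def partial_dependence(model: TrainedModel, variable: str,
                       grid_points=20) -> pd.DataFrame:
    """Average predicted probability as one feature sweeps its range.

    For each grid value v, the training rows are copied, the variable is
    forced to v everywhere, and predicted positive-class probabilities are
    averaged ("probability fraction mode").
    """
    if variable not in model.feature_names:
        raise KeyError(f"{variable!r} is not a model feature")
    col = model.X_train[variable].to_numpy(float)
    if np.isscalar(grid_points) and not hasattr(grid_points, "__len__"):
        values = np.linspace(col.min(), col.max(), int(grid_points))
    else:
        values = np.asarray(grid_points, dtype=float)
    yhat = []
    X = model.X_train.copy()
    for v in values:
        X[variable] = v
        yhat.append(float(model.predict_proba(X).mean()))
    return pd.DataFrame({variable: values, "yhat": yhat})


def evaluate(model: TrainedModel, X_test: pd.DataFrame, y_test,
             ) -> tuple[MetricSet, ConfusionMatrix]:
    """Test-set metrics at the 0.5 probability threshold, plus AUC.

    The reported ``auc_sd`` is the cross-validation SD carried by the
    model (uncertainty of the resampled AUC), not a test-set quantity.
    """
    y = np.asarray(y_test, dtype=bool)
    probs = model.predict_proba(X_test)
    cm = ConfusionMatrix.from_predictions(y, probs >= 0.5)
    base = metrics(cm)
    return (
        MetricSet(base.sensitivity, base.specificity, base.precision,
                  base.f1, base.accuracy,
                  auc=auc(probs, y), auc_sd=model.cv_auc_sd),
        cm,
    )
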