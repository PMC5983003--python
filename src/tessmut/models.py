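"""Model training and evaluation: cross-validation, combined classifier,
permutation controls, learning curves and stratified reports.

The learners are contract-level counterparts of the algorithms used in
the original Weka analyses: random forest (100 trees), RBF-kernel SVM
with probability calibration, decision tree (optionally bagged), a
one-hidden-layer perceptron with logistic activations, a reduced-error
pruned regression tree, and RBF-kernel support vector regression.
Regression predictions are additionally thresholded at −2.0 to yield
classification metrics.

Metric conventions: the positive class is ``"affected"`` (activity below
the −2.0 log2 threshold).  Se = TP/(TP+FN), Sp = TN/(TN+FP),
PPV = TP/(TP+FP), BAR = (Se+Sp)/2, MCC from the confusion counts, and
AUC via the rank (Mann–Whitney) statistic on positive-class
probabilities with ties averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .features import ACTIVITY_THRESHOLD, VariantDataset

POSITIVE_CLASS = "affected"
NEGATIVE_CLASS = "unaffected"
CLASSES = (POSITIVE_CLASS, NEGATIVE_CLASS)

CLASSIFIER_ALGORITHMS = ("rf", "svm", "dt", "nn")
REGRESSOR_ALGORITHMS = ("reptree", "svr")


class ModelError(ValueError):
    """Raised for invalid model configuration or inputs."""


@dataclass(frozen=True)
class LearnerSpec:
    """Algorithm choice plus hyperparameters; the seed is always explicit."""

    algorithm: str
    seed: int = 0
    hyperparameters: tuple[tuple[str, object], ...] = ()

    @property
    def task(self) -> str:
        if self.algorithm in CLASSIFIER_ALGORITHMS:
            return "classification"
        if self.algorithm in REGRESSOR_ALGORITHMS:
            return "regression"
        raise ModelError(f"unknown algorithm {self.algorithm!r}")

    def params(self) -> dict:
        return dict(self.hyperparameters)


class ReducedErrorPrunedTree(RegressorMixin, BaseEstimator):
    """Regression tree pruned against a held-out validation split.

    Grows a full tree, then selects the cost-complexity pruning level
    that minimizes squared error on an internal validation fraction and
    refits at that level on all training data.
    """

    def __init__(self, validation_fraction: float = 0.25, min_samples_leaf: int = 2,
                 random_state: int = 0):
        self.validation_fraction = validation_fraction
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        X_grow, X_val, y_grow, y_val = train_test_split(
            X, y, test_size=self.validation_fraction,
            random_state=self.random_state)
        base = DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf,
                                     random_state=self.random_state)
        path = base.cost_complexity_pruning_path(X_grow, y_grow)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        best_alpha, best_err = 0.0, np.inf
        for alpha in alphas:
            tree = DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf,
                                         random_state=self.random_state,
                                         ccp_alpha=float(alpha))
            tree.fit(X_grow, y_grow)
            err = float(np.mean((tree.predict(X_val) - y_val) ** 2))
            if err < best_err:
                best_alpha, best_err = float(alpha), err
        self.tree_ = DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf,
                                           random_state=self.random_state,
                                           ccp_alpha=best_alpha)
        self.tree_.fit(X, y)
        self.ccp_alpha_ = best_alpha
        return self

    def predict(self, X):
        return self.tree_.predict(np.asarray(X, dtype=float))


def make_learner(spec: LearnerSpec) -> BaseEstimator:
    """Instantiate the estimator for a learner spec."""
    hp = spec.params()
    algo = spec.algorithm
    if algo == "rf":
        return RandomForestClassifier(n_estimators=int(hp.get("trees", 100)),
                                      random_state=spec.seed)
    if algo == "svm":
        # inputs standardized as Weka's SMO normalizes by default;
        # probabilities via logistic (Platt) calibration
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=float(hp.get("C", 1.0)), gamma="scale",
                probability=True, random_state=spec.seed))
    if algo == "dt":
        bags = int(hp.get("bagging", 0))
        tree = DecisionTreeClassifier(random_state=spec.seed)
        if bags > 0:
            return BaggingClassifier(estimator=tree, n_estimators=bags,
                                     random_state=spec.seed)
        return tree
    if algo == "nn":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(int(hp.get("hidden", 16)),),
                          activation="logistic",
                          max_iter=int(hp.get("max_iter", 2000)),
                          random_state=spec.seed))
    if algo == "reptree":
        return ReducedErrorPrunedTree(random_state=spec.seed,
                                      min_samples_leaf=int(hp.get("min_samples_leaf", 2)))
    if algo == "svr":
        return make_pipeline(StandardScaler(),
                             SVR(kernel="rbf", C=float(hp.get("C", 1.0)),
                                 gamma="scale"))
    raise ModelError(f"unknown algorithm {algo!r}")


def encode_features(dataset: VariantDataset) -> pd.DataFrame:
    """Numeric design matrix: one-hot categoricals, deterministic column order."""
    X = dataset.frame[dataset.feature_columns]
    categorical = [c for c in X.columns if X[c].dtype == object]
    X = pd.get_dummies(X, columns=categorical, dtype=float)
    return X[sorted(X.columns)].astype(float)


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann–Whitney rank statistic, ties averaged."""
    y_true = np.asarray(y_true, dtype=bool)
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(y_true: Sequence[str], y_pred: Sequence[str],
                    proba_positive: Sequence[float] | None = None) -> dict[str, float]:
    """Confusion counts and the derived metric set.

    Metrics undefined for the given truth (single-class MCC/AUC, empty
    denominators) come back as NaN rather than raising.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ModelError("predictions and truth must be non-empty and aligned")
    pos_t = y_true == POSITIVE_CLASS
    pos_p = y_pred == POSITIVE_CLASS
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    bar = 0.5 * (se + sp)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else float("nan")
    auc = (rank_auc(pos_t, np.asarray(proba_positive, dtype=float))
           if proba_positive is not None else float("nan"))
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "Se": se, "Sp": sp,
            "PPV": ppv, "BAR": bar, "MCC": mcc, "AUC": auc}


@dataclass
class EvaluationResult:
    """Out-of-fold predictions plus the metric set for one CV run."""

    task: str
    scheme: str
    seed: int
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: pd.DataFrame | None
    y_score: np.ndarray | None
    metrics: dict[str, float]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def class_true(self) -> np.ndarray:
        if self.task == "classification":
            return self.y_true
        return np.where(self.y_true < ACTIVITY_THRESHOLD, POSITIVE_CLASS, NEGATIVE_CLASS)

    @property
    def class_pred(self) -> np.ndarray:
        if self.task == "classification":
            return self.y_pred
        return np.where(self.y_pred < ACTIVITY_THRESHOLD, POSITIVE_CLASS, NEGATIVE_CLASS)


def _folds(y: np.ndarray, scheme: str, seed: int, task: str):
    n = len(y)
    if scheme == "loo":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    if scheme.startswith("k"):
        k = int(scheme[1:])
        if task == "classification":
            counts = pd.Series(y).value_counts()
            if counts.min() < k:
                raise ModelError(
                    f"class {counts.idxmin()!r} has {counts.min()} rows, fewer than "
                    f"{k} folds; use larger folds or more data"
                )
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            return list(splitter.split(np.zeros(n), y))
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(n)))
    raise ModelError(f"unknown CV scheme {scheme!r} (use 'loo' or e.g. 'k10')")


def crossvalidate(dataset: VariantDataset, spec: LearnerSpec,
                  scheme: str = "k10", seed: int = 0,
                  y_override: np.ndarray | None = None) -> EvaluationResult:
    """Cross-validate a learner; every row is predicted exactly once.

    Classification folds are stratified by class; regression predictions
    are additionally thresholded at −2.0 so the usual classification
    metrics are reported alongside the Pearson r.
    """
    task = spec.task
    X = encode_features(dataset).to_numpy()
    if y_override is not None:
        y = np.asarray(y_override)
    elif task == "classification":
        y = dataset.frame["activity_class"].to_numpy()
    else:
        y = dataset.frame["log2_effect"].to_numpy(dtype=float)
    if task == "classification":
        present = set(np.unique(y))
        if not present <= set(CLASSES):
            raise ModelError(f"unexpected class labels {present - set(CLASSES)}")
        if len(present) < 2:
            raise ModelError("classification needs both classes present")

    n = len(y)
    y_pred = np.empty(n, dtype=object if task == "classification" else float)
    proba = pd.DataFrame(np.zeros((n, 2)), columns=list(CLASSES)) \
        if task == "classification" else None
    for train_idx, test_idx in _folds(y, scheme, seed, task):
        est = clone(make_learner(spec))
        est.fit(X[train_idx], y[train_idx])
        if task == "classification":
            prob = est.predict_proba(X[test_idx])
            order = {c: i for i, c in enumerate(est.classes_)}
            for cls in CLASSES:
                proba.iloc[test_idx, proba.columns.get_loc(cls)] = (
                    prob[:, order[cls]] if cls in order else 0.0
                )
            y_pred[test_idx] = est.predict(X[test_idx])
        else:
            y_pred[test_idx] = est.predict(X[test_idx])

    meta_cols = [c for c in ("variant", "chain") if c in dataset.frame.columns]
    meta = dataset.frame[meta_cols].reset_index(drop=True)
    if task == "classification":
        metrics = compute_metrics(y, y_pred, proba[POSITIVE_CLASS].to_numpy())
        return EvaluationResult(task, scheme, seed, y, y_pred, proba, None,
                                metrics, meta)
    r = float(pearsonr(y, y_pred.astype(float))[0]) if np.std(y_pred.astype(float)) > 0 else float("nan")
    cls_true = np.where(y < ACTIVITY_THRESHOLD, POSITIVE_CLASS, NEGATIVE_CLASS)
    cls_pred = np.where(y_pred.astype(float) < ACTIVITY_THRESHOLD,
                        POSITIVE_CLASS, NEGATIVE_CLASS)
    # lower (more negative) predicted activity means more likely affected
    metrics = compute_metrics(cls_true, cls_pred, -y_pred.astype(float))
    metrics["r"] = r
    return EvaluationResult(task, scheme, seed, y, y_pred, None,
                            y_pred.astype(float), metrics, meta)


def combined_classifier(probas: list[pd.DataFrame],
                        y_true: np.ndarray | None = None) -> dict:
    """Average class probabilities over classifiers; argmax predicts.

    Exact ties predict the positive ("affected") class — the
    conservative call.  With ``y_true`` given, the metric set of the
    combined predictions is included.
    """
    if len(probas) < 2:
        raise ModelError("combined classifier needs >= 2 probability sets")
    first = probas[0]
    for p in probas[1:]:
        if list(p.columns) != list(first.columns) or len(p) != len(first):
            raise ModelError("probability sets must share rows and class set")
    mean = sum(p.to_numpy() for p in probas) / len(probas)
    mean = pd.DataFrame(mean, columns=first.columns)
    pos = mean[POSITIVE_CLASS].to_numpy()
    neg = mean[NEGATIVE_CLASS].to_numpy()
    predictions = np.where(pos >= neg, POSITIVE_CLASS, NEGATIVE_CLASS)
    out = {"proba": mean, "predictions": predictions}
    if y_true is not None:
        out["metrics"] = compute_metrics(y_true, predictions, pos)
    return out


def permutation_control(dataset: VariantDataset, spec: LearnerSpec,
                        scheme: str = "k10", n_shuffles: int = 100,
                        seed: int = 0) -> dict:
    """Label-shuffling null distribution for a CV protocol.

    The output attribute is permuted among rows (inputs untouched) and
    the identical CV protocol rerun per shuffle.  Reports the observed
    result, per-shuffle BAR/MCC (or r), their mean ± sd, and the
    empirical p — the fraction of shuffles with a statistic at least as
    large as observed.
    """
    if n_shuffles < 1:
        raise ModelError("n_shuffles must be >= 1")
    observed = crossvalidate(dataset, spec, scheme=scheme, seed=seed)
    task = spec.task
    y = (dataset.frame["activity_class"] if task == "classification"
         else dataset.frame["log2_effect"]).to_numpy()
    rng = np.random.default_rng(seed)
    keys = ("BAR", "MCC") if task == "classification" else ("r",)
    null: dict[str, list[float]] = {k: [] for k in keys}
    for _ in range(n_shuffles):
        shuffled = y[rng.permutation(len(y))]
        result = crossvalidate(dataset, spec, scheme=scheme, seed=seed,
                               y_override=shuffled)
        for k in keys:
            null[k].append(result.metrics[k])
    summary = {
        "observed": observed.metrics,
        "n_shuffles": n_shuffles,
        "null": {k: np.asarray(v) for k, v in null.items()},
    }
    for k in keys:
        arr = np.asarray(null[k], dtype=float)
        summary[f"null_{k}_mean"] = float(np.nanmean(arr))
        summary[f"null_{k}_sd"] = float(np.nanstd(arr, ddof=1)) if n_shuffles > 1 else 0.0
        summary[f"p_{k}"] = float(np.mean(arr >= observed.metrics[k]))
    return summary


def learning_curve(dataset: VariantDataset, spec: LearnerSpec,
                   sizes: Sequence[int], reps: int = 10,
                   scheme: str = "k10", seed: int = 0) -> pd.DataFrame:
    """Mean ± sd of BAR/MCC/AUC over stratified subsamples of each size."""
    n = len(dataset.frame)
    if max(sizes) > n:
        raise ModelError(f"max size {max(sizes)} exceeds dataset size {n}")
    if min(sizes) < 20:
        raise ModelError("sizes below 20 rows give degenerate folds")
    rng = np.random.default_rng(seed)
    y = dataset.frame[dataset.output_column].to_numpy()
    rows = []
    for size in sizes:
        per_rep = {"BAR": [], "MCC": [], "AUC": []}
        for _rep in range(reps):
            if spec.task == "classification":
                idx_parts = []
                for cls in np.unique(y):
                    cls_idx = np.flatnonzero(y == cls)
                    take = int(round(size * len(cls_idx) / n))
                    idx_parts.append(rng.choice(cls_idx, size=max(take, 1), replace=False))
                idx = np.sort(np.concatenate(idx_parts))
            else:
                idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = VariantDataset(frame=dataset.frame.iloc[idx].reset_index(drop=True),
                                 mode=dataset.mode, task=dataset.task)
            res = crossvalidate(sub, spec, scheme=scheme,
                                seed=int(rng.integers(2 ** 31 - 1)))
            for k in per_rep:
                per_rep[k].append(res.metrics[k])
        for metric, values in per_rep.items():
            arr = np.asarray(values, dtype=float)
            rows.append({"size": size, "metric": metric,
                         "mean": float(np.nanmean(arr)),
                         "sd": float(np.nanstd(arr, ddof=1)) if reps > 1 else 0.0,
                         "reps": reps})
    return pd.DataFrame(rows)


def stratified_performance(result: EvaluationResult,
                           groups: Sequence) -> pd.DataFrame:
    """Per-group BAR/MCC plus group composition percentages.

    ``groups`` must align with the evaluation rows and partition them;
    composition percentages sum to 100.  Empty metric denominators
    within a group come back as NaN.
    """
    groups = np.asarray(groups)
    if len(groups) != len(result.y_true):
        raise ModelError("groups must align with evaluation rows")
    cls_true, cls_pred = result.class_true, result.class_pred
    rows = []
    total = len(groups)
    for g in pd.unique(groups):
        mask = groups == g
        m = compute_metrics(cls_true[mask], cls_pred[mask])
        rows.append({"group": g, "n": int(mask.sum()),
                     "pct": 100.0 * mask.sum() / total,
                     "BAR": m["BAR"], "MCC": m["MCC"]})
    return pd.DataFrame(rows)


def prediction_array(result: EvaluationResult) -> pd.DataFrame:
    """Position × replacement grid of prediction outcomes.

    Cells are ``correct`` / ``incorrect`` for evaluated variants,
    ``not-a-variant`` where native and replacement coincide, and
    ``no-data`` elsewhere.  Columns are (chain, position, native)
    triples when chain metadata is present.
    """
    if "variant" not in result.meta.columns:
        raise ModelError("prediction_array needs variant identities in metadata")
    from .mutagenesis import parse_variant
    from .structure_io import AMINO_ACIDS

    cls_true, cls_pred = result.class_true, result.class_pred
    cells: dict[tuple, dict[str, str]] = {}
    natives: dict[tuple, str] = {}
    for i, vstr in enumerate(result.meta["variant"]):
        v = parse_variant(vstr)
        chain = result.meta["chain"].iloc[i] if "chain" in result.meta.columns else ""
        col = (chain, v.position)
        natives[col] = v.native
        outcome = "correct" if cls_true[i] == cls_pred[i] else "incorrect"
        cells.setdefault(col, {})[v.replacement] = outcome
    columns = sorted(natives)
    grid = pd.DataFrame("no-data", index=list(AMINO_ACIDS),
                        columns=pd.MultiIndex.from_tuples(
                            [(c, p, natives[(c, p)]) for c, p in columns],
                            names=["chain", "position", "native"]))
    for (chain, pos), outcomes in cells.items():
        native = natives[(chain, pos)]
        grid.loc[native, (chain, pos, native)] = "not-a-variant"
        for replacement, outcome in outcomes.items():
            grid.loc[replacement, (chain, pos, native)] = outcome
    for col, native in natives.items():
        grid.loc[native, (col[0], col[1], native)] = "not-a-variant"
    return grid
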