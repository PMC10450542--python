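"""Nested leave-one-participant-out evaluation, stacking, and metrics.

Outer loop: leave-one-participant-out.  Inside each outer training fold the
scaler, the label-aware hamming-ratio features, the feature selector and each
model's hyperparameters are recomputed from the n-1 training participants
only.  Inner tuning: stratified k-fold (default 20) maximizing F1 with a
random-search budget.  The stacking model ranks base learners by outer F1 and
trains a logistic meta-learner on stratified 10-fold out-of-fold predictions
within each outer training fold.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import Selector
from .markers import HammingIndex

# --------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class EvalReport:
    """Confusion-derived evaluation metrics; zero denominators yield 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    balanced_accuracy: float
    auc: float | None = None


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    return (sensitivity + specificity) / 2.0


def metrics(
    tp: int,
    fp: int,
    tn: int,
    fn: int,
    y_true: Sequence[int] | None = None,
    scores: Sequence[float] | None = None,
) -> EvalReport:
    """Build an EvalReport from confusion counts (plus optional AUC inputs)."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("confusion counts must be nonnegative with a positive total")
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity)
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    auc = None
    if y_true is not None and scores is not None and len(set(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return EvalReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        accuracy=accuracy,
        balanced_accuracy=balanced_accuracy(sensitivity, specificity),
        auc=auc,
    )


def report_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], scores: Sequence[float] | None = None
) -> EvalReport:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    return metrics(tp, fp, tn, fn, y_true=yt, scores=scores)


# --------------------------------------------------------------------------
# model zoo


@dataclass(frozen=True)
class ModelSpec:
    name: str
    factory: Callable[[int], object]
    space: Mapping[str, Sequence]


def default_zoo(include: Sequence[str] | None = None) -> dict[str, ModelSpec]:
    """The configurable classifier zoo (sklearn estimators only).

    ``hist_gradient_boosting`` is the histogram-GBM family member; SVM kernels
    are one family with kernel as a hyperparameter.
    """
    specs = {
        "dummy": ModelSpec(
            "dummy",
            lambda seed: DummyClassifier(strategy="constant", constant=1),
            {},
        ),
        "logit": ModelSpec(
            "logit",
            lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "decision_tree": ModelSpec(
            "decision_tree",
            lambda seed: DecisionTreeClassifier(random_state=seed),
            {"max_depth": [2, 3, 5, 8, None], "min_samples_leaf": [1, 2, 5]},
        ),
        "random_forest": ModelSpec(
            "random_forest",
            lambda seed: RandomForestClassifier(
                n_estimators=100, random_state=seed, n_jobs=1
            ),
            {"n_estimators": [50, 100, 200], "max_depth": [None, 3, 5, 8]},
        ),
        "extra_trees": ModelSpec(
            "extra_trees",
            lambda seed: ExtraTreesClassifier(
                n_estimators=100, random_state=seed, n_jobs=1
            ),
            {"n_estimators": [50, 100, 200], "max_depth": [None, 3, 5, 8]},
        ),
        "knn": ModelSpec(
            "knn",
            lambda seed: KNeighborsClassifier(),
            {"n_neighbors": [3, 5, 7, 9, 11], "weights": ["uniform", "distance"]},
        ),
        "gaussian_nb": ModelSpec(
            "gaussian_nb",
            lambda seed: GaussianNB(),
            {"var_smoothing": [1e-9, 1e-8, 1e-7]},
        ),
        "svm": ModelSpec(
            "svm",
            lambda seed: SVC(probability=True, random_state=seed),
            {"C": [0.1, 1.0, 10.0], "gamma": ["scale", "auto"], "kernel": ["rbf", "linear"]},
        ),
        "adaboost": ModelSpec(
            "adaboost",
            lambda seed: AdaBoostClassifier(random_state=seed),
            {"n_estimators": [25, 50, 100], "learning_rate": [0.5, 1.0]},
        ),
        "gradient_boosting": ModelSpec(
            "gradient_boosting",
            lambda seed: GradientBoostingClassifier(random_state=seed),
            {"n_estimators": [50, 100], "learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
        ),
        "hist_gradient_boosting": ModelSpec(
            "hist_gradient_boosting",
            lambda seed: HistGradientBoostingClassifier(random_state=seed),
            {"max_iter": [50, 100], "learning_rate": [0.05, 0.1], "max_depth": [None, 3, 6]},
        ),
        "mlp": ModelSpec(
            "mlp",
            lambda seed: MLPClassifier(max_iter=500, random_state=seed),
            {"hidden_layer_sizes": [(16,), (32,), (64,)], "alpha": [1e-4, 1e-3, 1e-2]},
        ),
    }
    if include is not None:
        missing = set(include) - set(specs)
        if missing:
            raise KeyError(f"unknown zoo members: {sorted(missing)}")
        specs = {k: specs[k] for k in include}
    return specs


@dataclass(frozen=True)
class TuningConfig:
    budget: int = 10  # random-search evaluations per model per fold; 0 = defaults
    inner_folds: int = 20


def fold_seed(seed: int, heldout_id: str) -> int:
    """Fold-local seed, stable under deletion of the held-out row."""
    return zlib.crc32(f"{seed}:{heldout_id}".encode()) & 0x7FFFFFFF


def _score_of(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict(X).astype(float)


def tune_model(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    tuning: TuningConfig,
    seed: int,
) -> dict:
    """Random search over the spec's grid, maximizing inner-CV mean F1."""
    if tuning.budget <= 0 or not spec.space:
        return {}
    classes, counts = np.unique(y, return_counts=True)
    n_splits = int(min(tuning.inner_folds, counts.min()))
    if n_splits < 2:
        return {}
    grid_size = int(np.prod([len(v) for v in spec.space.values()]))
    sampler = ParameterSampler(
        dict(spec.space), n_iter=min(tuning.budget, grid_size), random_state=seed
    )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_params, best_score = {}, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=UserWarning)
        for params in sampler:
            scores = []
            for tr, va in splits:
                model = spec.factory(seed)
                model.set_params(**params)
                model.fit(X[tr], y[tr])
                scores.append(f1_score(y[va], model.predict(X[va]), zero_division=0))
            mean = float(np.mean(scores))
            if mean > best_score:
                best_score, best_params = mean, params
    return best_params


# --------------------------------------------------------------------------
# nested LOPOCV


@dataclass
class FoldFit:
    """Everything derived from one outer training fold (no test-row input)."""

    scaler_mean: pd.Series
    scaler_sd: pd.Series
    selected: list[str]
    params: dict[str, dict]
    models: dict[str, object]

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = (rows - self.scaler_mean) / self.scaler_sd.replace(0.0, np.nan)
        out[self.scaler_sd.index[self.scaler_sd == 0.0]] = 0.0
        return out.fillna(0.0)


@dataclass
class FoldResult:
    heldout_id: str
    selected: list[str]
    params: dict[str, dict]
    predictions: dict[str, tuple[int, float]]  # model -> (label, score)


@dataclass
class LopoResult:
    reports: dict[str, EvalReport]
    folds: list[FoldResult]
    y_true: pd.Series


def fit_fold(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    selector: Selector,
    zoo: Mapping[str, ModelSpec],
    tuning: TuningConfig,
    seed: int,
) -> FoldFit:
    """Fit scaler, selector and tuned models from training rows only."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    fit = FoldFit(scaler_mean=mean, scaler_sd=sd, selected=[], params={}, models={})
    X_scaled = fit.transform(X_train)
    y = y_train.to_numpy().astype(int)
    fit.selected = list(selector(X_scaled, y, seed))
    Xs = X_scaled[fit.selected].to_numpy() if fit.selected else X_scaled.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for name, spec in zoo.items():
            params = tune_model(spec, Xs, y, tuning, seed)
            model = spec.factory(seed)
            if params:
                model.set_params(**params)
            model.fit(Xs, y)
            fit.params[name] = params
            fit.models[name] = model
    return fit


def _hamming_scopes(index: HammingIndex, columns: Sequence[str]) -> list[str]:
    cols = set(columns)
    out = []
    for scope in index.scopes:
        tok = scope.replace(" ", "_")
        if any(
            f"{day}_{tok}_Ratio_of_Hamming_{char}" in cols
            for day in ("Weekday", "Weekend")
            for char in ("6_Hour_Mean", "6_Hour_SD", "Total")
        ):
            out.append(scope)
    return out


def _fold_matrices(
    matrix: pd.DataFrame,
    labels: Mapping[str, int],
    heldout: str,
    hamming_index: HammingIndex | None,
    scopes: list[str] | None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Training matrix, held-out row and training labels for one outer fold.

    Hamming-ratio columns are recomputed with training-fold comparator pools
    only; the held-out participant's ratios use those same pools.
    """
    train_ids = [p for p in matrix.index if p != heldout]
    work = matrix
    if hamming_index is not None and scopes:
        train_labels = {p: labels[p] for p in train_ids}
        ham = hamming_index.ratio_columns(train_labels, scopes=scopes)
        cols = [c for c in ham.columns if c in matrix.columns]
        work = matrix.copy()
        work.loc[:, cols] = ham.loc[work.index, cols]
    y_train = pd.Series({p: int(labels[p]) for p in train_ids}, name="label")
    # tolerate an already-deleted held-out row (leakage audits recompute folds
    # from a cohort with that participant removed)
    test = work.loc[[heldout]] if heldout in work.index else work.iloc[0:0]
    return work.loc[train_ids], test, y_train


def nested_lopocv(
    matrix: pd.DataFrame,
    labels: Mapping[str, int],
    selector: Selector,
    zoo: Mapping[str, ModelSpec] | None = None,
    tuning: TuningConfig | None = None,
    seed: int = 0,
    hamming_index: HammingIndex | None = None,
) -> LopoResult:
    """Leave-one-participant-out evaluation with inner tuning and selection.

    Every fold-level artifact (scaler, hamming pools, selected features, tuned
    hyperparameters) is a function of the n-1 training rows and the fold seed
    only; the held-out row never participates.
    """
    zoo = zoo if zoo is not None else default_zoo()
    tuning = tuning if tuning is not None else TuningConfig()
    pids = list(matrix.index)
    y_all = pd.Series({p: int(labels[p]) for p in pids})
    if y_all.nunique() < 2 or y_all.value_counts().min() < 2:
        raise ValueError("need at least 2 participants per class")

    scopes = (
        _hamming_scopes(hamming_index, matrix.columns) if hamming_index is not None else None
    )

    folds: list[FoldResult] = []
    preds: dict[str, list[int]] = {name: [] for name in zoo}
    scores: dict[str, list[float]] = {name: [] for name in zoo}

    for pid in pids:
        X_train, x_test, y_train = _fold_matrices(
            matrix, labels, pid, hamming_index, scopes
        )
        fseed = fold_seed(seed, pid)
        fit = fit_fold(X_train, y_train, selector, zoo, tuning, fseed)
        x_scaled = fit.transform(x_test)
        xs = x_scaled[fit.selected].to_numpy() if fit.selected else x_scaled.to_numpy()
        fold_preds = {}
        for name, model in fit.models.items():
            label = int(model.predict(xs)[0])
            score = float(_score_of(model, xs)[0])
            fold_preds[name] = (label, score)
            preds[name].append(label)
            scores[name].append(score)
        folds.append(
            FoldResult(
                heldout_id=pid,
                selected=fit.selected,
                params=fit.params,
                predictions=fold_preds,
            )
        )

    reports = {
        name: report_from_predictions(y_all.to_numpy(), preds[name], scores[name])
        for name in zoo
    }
    return LopoResult(reports=reports, folds=folds, y_true=y_all)


# --------------------------------------------------------------------------
# stacking


def rank_models(reports: Mapping[str, EvalReport], exclude: Sequence[str] = ("dummy",)) -> list[str]:
    """Model names by F1 desc, ties by precision desc then name asc."""
    names = [n for n in reports if n not in exclude]
    return sorted(names, key=lambda n: (-reports[n].f1, -reports[n].precision, n))


def stack_top5(
    matrix: pd.DataFrame,
    labels: Mapping[str, int],
    lopo: LopoResult,
    zoo: Mapping[str, ModelSpec] | None = None,
    seed: int = 0,
    hamming_index: HammingIndex | None = None,
    n_base: int = 5,
    meta_folds: int = 10,
) -> tuple[EvalReport, list[str]]:
    """Stacking ensemble over the top-n_base models from a LOPOCV run.

    Per outer fold: base learners (with that fold's tuned hyperparameters)
    produce stratified ``meta_folds``-fold out-of-fold probabilities on the
    training rows; a logistic meta-learner is fit on them and predicts the
    held-out participant from the refit base learners' probabilities.
    """
    zoo = zoo if zoo is not None else default_zoo()
    ranked = rank_models(lopo.reports)
    if len(ranked) < n_base:
        raise ValueError(f"need at least {n_base} non-dummy models, got {len(ranked)}")
    top = ranked[:n_base]
    scopes = (
        _hamming_scopes(hamming_index, matrix.columns) if hamming_index is not None else None
    )

    y_true, y_pred, y_score = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for fr in lopo.folds:
            pid = fr.heldout_id
            X_train, x_test, y_train = _fold_matrices(
                matrix, labels, pid, hamming_index, scopes
            )
            fseed = fold_seed(seed, pid)
            mean = X_train.mean(axis=0)
            sd = X_train.std(axis=0, ddof=0)
            holder = FoldFit(mean, sd, fr.selected, {}, {})
            Xs = holder.transform(X_train)[fr.selected].to_numpy()
            xt = holder.transform(x_test)[fr.selected].to_numpy()
            y = y_train.to_numpy().astype(int)

            counts = np.unique(y, return_counts=True)[1]
            n_splits = int(min(meta_folds, counts.min()))
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=fseed)

            oof = np.zeros((len(y), len(top)))
            test_feats = np.zeros((1, len(top)))
            for j, name in enumerate(top):
                est = zoo[name].factory(fseed)
                if fr.params.get(name):
                    est.set_params(**fr.params[name])
                oof[:, j] = cross_val_predict(
                    clone(est), Xs, y, cv=skf, method="predict_proba"
                )[:, 1]
                est.fit(Xs, y)
                test_feats[0, j] = est.predict_proba(xt)[0, 1]

            meta = LogisticRegression(max_iter=2000, random_state=fseed)
            meta.fit(oof, y)
            y_true.append(int(labels[pid]))
            y_pred.append(int(meta.predict(test_feats)[0]))
            y_score.append(float(meta.predict_proba(test_feats)[0, 1]))

    return report_from_predictions(y_true, y_pred, y_score), top


# --------------------------------------------------------------------------
# importance summaries


def appearance_frequency(folds: Sequence[FoldResult]) -> pd.Series:
    """Percentage of LOPOCV iterations whose selection contains each feature."""
    if not folds:
        return pd.Series(dtype=float)
    counts: dict[str, int] = {}
    for fr in folds:
        for name in fr.selected:
            counts[name] = counts.get(name, 0) + 1
    pct = pd.Series(counts, dtype=float) * 100.0 / len(folds)
    return pct.sort_values(ascending=False)


def attributions(
    model, X: pd.DataFrame, y: Sequence[int], seed: int = 0, n_repeats: int = 10
) -> pd.DataFrame:
    """Seeded permutation-importance attribution table for a fitted model."""
    from sklearn.inspection import permutation_importance

    res = permutation_importance(
        model, X.to_numpy(), np.asarray(y).astype(int), n_repeats=n_repeats,
        random_state=seed,
    )
    return pd.DataFrame(
        {
            "feature": list(X.columns),
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    ).sort_values("importance_mean", ascending=False, ignore_index=True)
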