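"""Training and tuning of the six GPR prediction models.

Three algorithms — a single-hidden-layer feed-forward neural network
(ANN), a support vector machine with RBF kernel (SVM) and a random
forest (RF) — each in a regression flavour (predict GPR %) and a
classification flavour (predict the fail=1 / pass=0 QA outcome).

Tuning protocol: ANN and SVM scan their hyperparameter grids jointly by
ten-fold cross-validation (regression: minimise CV RMSE; classification:
maximise CV AUC).  RF tunes in two stages, mirroring common practice
with the randomForest toolchain: ``mtry`` (features per split) first by
out-of-bag error at a fixed tree count, then ``ntree`` by ten-fold CV
at the chosen ``mtry``.  Ties break toward the earlier grid point.
ANN/SVM inputs are standardized to zero mean / unit SD on the training
set; RF consumes raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from planqa.evaluation import QARecord, auc as _auc
from planqa.features import FEATURE_NAMES

ALGORITHMS = ("ann", "svm", "rf")
TASKS = ("regression", "classification")

#: Default hyperparameter grids.  Centres cover the optima typically
#: found for cohorts of a few thousand IMRT fields (ANN ~10-20 hidden
#: nodes; SVM cost around 1-8 with gamma near 1/n_features; RF mtry in
#: the single digits with a few hundred trees).
DEFAULT_GRIDS = {
    "ann": {"hidden_nodes": list(range(3, 26, 2)), "weight_decay": [0.0, 0.01, 0.1]},
    "svm": {"cost": [0.25, 0.5, 1, 2, 4, 8, 16], "gamma": [0.02, 0.05, 0.1, 0.14, 0.2, 0.5]},
    "rf": {"mtry": list(range(2, 22)), "ntree": list(range(100, 501, 25))},
}

#: Reduced grids spanning the same hyperparameter region as
#: DEFAULT_GRIDS at a fraction of the fit count; the preset for studies
#: on a single CPU where the full scan adds little.
COMPACT_GRIDS = {
    "ann": {"hidden_nodes": [9, 19], "weight_decay": [0.01]},
    "svm": {"cost": [1, 8], "gamma": [0.05, 0.14]},
    "rf": {"mtry": [2, 5, 9, 15], "ntree": [150, 300]},
}

#: Fixed tree count used during the RF mtry (out-of-bag) stage.
RF_MTRY_STAGE_NTREE = 300


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    task: str
    tuning_grid: dict = dc_field(default_factory=dict)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        grid = self.grid
        if any(len(v) == 0 for v in grid.values()):
            raise ValueError("tuning grid lists must be non-empty")
        if self.algorithm == "svm":
            if any(c <= 0 for c in grid["cost"]) or any(g <= 0 for g in grid["gamma"]):
                raise ValueError("svm cost and gamma must be positive")
        if self.algorithm == "rf" and max(grid["mtry"]) > len(FEATURE_NAMES):
            raise ValueError(f"rf mtry cannot exceed {len(FEATURE_NAMES)} features")

    @property
    def grid(self) -> dict:
        return self.tuning_grid or DEFAULT_GRIDS[self.algorithm]


@dataclass
class FittedModel:
    """One trained (algorithm, task) pair with its tuning trace.

    ``tuning_trace`` is a list of dicts, one per evaluated grid point,
    with the hyperparameters, the stage label (``"cv"`` for the joint
    CV scan, ``"oob_mtry"`` / ``"cv_ntree"`` for the RF stages, in
    evaluation order) and the score (CV RMSE, OOB error, or CV AUC).
    """

    config: ModelConfig
    chosen_hyperparameters: dict
    tuning_trace: list
    estimator: object
    scaler: StandardScaler | None
    feature_names: tuple = FEATURE_NAMES
    train_predictions: np.ndarray | None = None


def records_to_xy(records: list[QARecord], task: str):
    X = np.array([[r.features[k] for k in FEATURE_NAMES] for r in records], dtype=float)
    y = (np.array([r.gpr for r in records], dtype=float) if task == "regression"
         else np.array([r.label for r in records], dtype=int))
    return X, y


def split_dataset(records: list[QARecord], test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[list[QARecord], list[QARecord]]:
    """Random, unstratified train/test partition.

    ``|test| = round(n · test_fraction)``; with the cohort size 2340 and
    the default 8:2 ratio this gives 1872 training and 468 test fields.
    """
    n = len(records)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_test = int(round(n * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [records[i] for i in range(n) if i not in test_idx]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


def _make_estimator(algorithm: str, task: str, hp: dict, seed: int):
    if algorithm == "ann":
        cls = MLPRegressor if task == "regression" else MLPClassifier
        return cls(hidden_layer_sizes=(int(hp["hidden_nodes"]),), alpha=float(hp["weight_decay"]),
                   solver="lbfgs", max_iter=500, random_state=seed)
    if algorithm == "svm":
        if task == "regression":
            return SVR(C=float(hp["cost"]), gamma=float(hp["gamma"]))
        return SVC(C=float(hp["cost"]), gamma=float(hp["gamma"]), probability=True,
                   random_state=seed)
    cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
    return cls(n_estimators=int(hp["ntree"]), max_features=int(hp["mtry"]),
               random_state=seed, n_jobs=1)


def _scores_from(est, X, task: str) -> np.ndarray:
    """Continuous prediction: GPR % (regression) or fail probability (classification)."""
    if task == "regression":
        return np.asarray(est.predict(X), dtype=float)
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        return np.asarray(proba[:, list(est.classes_).index(1)], dtype=float)
    return np.asarray(est.decision_function(X), dtype=float)


def _cv_score(algorithm: str, task: str, hp: dict, X, y, cv_folds: int, seed: int) -> float:
    """CV RMSE (regression, lower better) or CV AUC (classification, higher better)."""
    splitter = (KFold(cv_folds, shuffle=True, random_state=seed) if task == "regression"
                else StratifiedKFold(cv_folds, shuffle=True, random_state=seed))
    preds = np.empty(len(y), dtype=float)
    for tr, va in splitter.split(X, y if task == "classification" else None):
        est = _make_estimator(algorithm, task, hp, seed)
        if algorithm == "svm" and task == "classification":
            # Platt scaling is not needed for a rank metric; use the margin.
            est = SVC(C=float(hp["cost"]), gamma=float(hp["gamma"]), random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        if task == "regression":
            preds[va] = est.predict(X[va])
        else:
            preds[va] = (est.decision_function(X[va]) if isinstance(est, SVC) and not est.probability
                         else _scores_from(est, X[va], task))
    if task == "regression":
        return float(np.sqrt(np.mean((preds - y) ** 2)))
    return _auc(preds, y)


def _grid_points(grid: dict, keys: list[str]):
    from itertools import product

    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def tune_and_train(config: ModelConfig, train: list[QARecord]) -> FittedModel:
    """Grid-search the hyperparameters by the declared protocol and refit on all of ``train``.

    Raises on a single-class classification training set or non-finite
    features.
    """
    X, y = records_to_xy(train, config.task)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features in training data")
    if config.task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification training set contains a single class")

    scaler = None
    Xs = X
    if config.algorithm in ("ann", "svm"):
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)

    trace: list[dict] = []
    minimize = config.task == "regression"

    if config.algorithm == "rf":
        chosen = _tune_rf(config, Xs, y, trace)
    else:
        keys = list(config.grid.keys())
        best, best_score = None, None
        for hp in _grid_points(config.grid, keys):
            score = _cv_score(config.algorithm, config.task, hp, Xs, y,
                              config.cv_folds, config.seed)
            trace.append({**hp, "stage": "cv", "score": score})
            better = (best is None or
                      (minimize and score < best_score) or
                      (not minimize and score > best_score))
            if better:
                best, best_score = hp, score
        chosen = best

    est = _make_estimator(config.algorithm, config.task, chosen, config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xs, y)
    model = FittedModel(config=config, chosen_hyperparameters=chosen, tuning_trace=trace,
                        estimator=est, scaler=scaler)
    model.train_predictions = _scores_from(est, Xs, config.task)
    model._train_X, model._train_y = Xs, y  # kept for OOB permutation importance
    return model


def _tune_rf(config: ModelConfig, X, y, trace: list) -> dict:
    """Two-stage RF tuning: mtry by OOB error first, then ntree by CV."""
    grid = config.grid
    is_reg = config.task == "regression"
    best_mtry, best_err = None, None
    for mtry in grid["mtry"]:
        cls = RandomForestRegressor if is_reg else RandomForestClassifier
        est = cls(n_estimators=RF_MTRY_STAGE_NTREE, max_features=int(mtry),
                  oob_score=True, bootstrap=True, random_state=config.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        if is_reg:
            oob = est.oob_prediction_
            err = float(np.mean((oob - y) ** 2))
        else:
            dec = est.oob_decision_function_
            pred = est.classes_[np.nanargmax(np.nan_to_num(dec), axis=1)]
            err = float(np.mean(pred != y))
        trace.append({"mtry": int(mtry), "ntree": RF_MTRY_STAGE_NTREE,
                      "stage": "oob_mtry", "score": err})
        if best_err is None or err < best_err:
            best_mtry, best_err = int(mtry), err
    best_ntree, best_score = None, None
    minimize = is_reg
    for ntree in grid["ntree"]:
        hp = {"mtry": best_mtry, "ntree": int(ntree)}
        score = _cv_score("rf", config.task, hp, X, y, config.cv_folds, config.seed)
        trace.append({**hp, "stage": "cv_ntree", "score": score})
        better = (best_ntree is None or
                  (minimize and score < best_score) or
                  (not minimize and score > best_score))
        if better:
            best_ntree, best_score = int(ntree), score
    return {"mtry": best_mtry, "ntree": best_ntree}


def predict(model: FittedModel, records: list[QARecord]) -> np.ndarray:
    """Predicted GPR % (regression) or fail-probability score in [0, 1]
    (classification); the hard classification label is ``score >= 0.5``."""
    X = np.array([[r.features[k] for k in model.feature_names] for r in records], dtype=float)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return _scores_from(model.estimator, X, model.config.task)


def feature_importance(model: FittedModel) -> list[tuple[str, float]]:
    """Permutation importance of a random-forest model, descending.

    For each feature the out-of-bag predictions are recomputed with
    that column permuted; the importance is the increase in OOB MSE
    (regression) or the decrease in OOB accuracy (classification).
    Falls back to whole-training-set permutation importance if the
    per-tree bootstrap indices are unavailable.
    """
    if model.config.algorithm != "rf":
        raise ValueError("feature importance is defined for random-forest models only")
    est = model.estimator
    X, y = model._train_X, model._train_y
    rng = np.random.default_rng(model.config.seed + 1)
    is_reg = model.config.task == "regression"

    try:
        from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

        n = X.shape[0]
        n_boot = _get_n_samples_bootstrap(n, est.max_samples)
        oob_masks = []
        for tree in est.estimators_:
            unsampled = _generate_unsampled_indices(tree.random_state, n, n_boot)
            mask = np.zeros(n, dtype=bool)
            mask[unsampled] = True
            oob_masks.append(mask)

        def oob_error(Xq: np.ndarray) -> float:
            agg = np.zeros(n)
            cnt = np.zeros(n)
            for tree, mask in zip(est.estimators_, oob_masks):
                if not mask.any():
                    continue
                pred = tree.predict(Xq[mask])
                if not is_reg:
                    pred = pred if pred.ndim == 1 else pred
                agg[mask] += pred
                cnt[mask] += 1
            have = cnt > 0
            avg = agg[have] / cnt[have]
            if is_reg:
                return float(np.mean((avg - y[have]) ** 2))
            return float(np.mean((avg >= 0.5).astype(int) != y[have]))

        base = oob_error(X)
        imps = []
        for j, name in enumerate(model.feature_names):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            imps.append((name, oob_error(Xp) - base))
    except Exception:  # pragma: no cover - version-dependent private API
        from sklearn.inspection import permutation_importance

        scoring = "neg_mean_squared_error" if is_reg else "accuracy"
        r = permutation_importance(est, X, y, scoring=scoring, n_repeats=5,
                                   random_state=model.config.seed + 1)
        imps = list(zip(model.feature_names, r.importances_mean))
    return sorted(imps, key=lambda kv: -kv[1])


def learning_curve(records: list[QARecord], config: ModelConfig,
                   fractions: tuple = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2)),
                   replicates: int = 3, seed: int = 0, test_fraction: float = 0.2,
                   fixed_hyperparameters: dict | None = None):
    """Model error (regression: RMSE) or AUC (classification) versus training-set size.

    A fixed held-out test set is split off first; for each of the 20
    sample fractions, ``replicates`` random subsets of the training
    pool are drawn and a model is trained on each (re-tuned from the
    grid, or with ``fixed_hyperparameters`` when supplied), and the
    train/test scores averaged.  Fractions whose subset would fall
    below ``cv_folds`` samples are skipped with a warning.

    Returns a DataFrame with columns fraction, n_train, train_score,
    test_score.
    """
    import pandas as pd

    train_pool, test = split_dataset(records, test_fraction, seed)
    Xte, yte = records_to_xy(test, config.task)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * len(train_pool)))
        if n_sub < config.cv_folds or n_sub < 5:
            warnings.warn(f"fraction {frac}: {n_sub} samples too few; point skipped", stacklevel=2)
            continue
        tr_scores, te_scores = [], []
        for _ in range(replicates):
            idx = rng.choice(len(train_pool), size=n_sub, replace=False)
            sub = [train_pool[i] for i in idx]
            if config.task == "classification" and len({r.label for r in sub}) < 2:
                continue
            if fixed_hyperparameters is None:
                model = tune_and_train(config, sub)
            else:
                model = _fit_fixed(config, sub, fixed_hyperparameters)
            tr_scores.append(_score_records(model, sub))
            te_scores.append(_score_records(model, test, (Xte, yte)))
        if tr_scores:
            rows.append({"fraction": float(frac), "n_train": n_sub,
                         "train_score": float(np.mean(tr_scores)),
                         "test_score": float(np.mean(te_scores))})
    return pd.DataFrame(rows)


def _fit_fixed(config: ModelConfig, train: list[QARecord], hp: dict) -> FittedModel:
    X, y = records_to_xy(train, config.task)
    scaler = None
    if config.algorithm in ("ann", "svm"):
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = _make_estimator(config.algorithm, config.task, hp, config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    m = FittedModel(config=config, chosen_hyperparameters=dict(hp), tuning_trace=[],
                    estimator=est, scaler=scaler)
    m._train_X, m._train_y = X, y
    return m


def _score_records(model: FittedModel, records, xy=None) -> float:
    _, y = xy if xy is not None else records_to_xy(records, model.config.task)
    scores = predict(model, records)
    if model.config.task == "regression":
        return float(np.sqrt(np.mean((scores - y) ** 2)))
    if len(np.unique(y)) < 2:
        return float("nan")
    return _auc(scores, y)
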