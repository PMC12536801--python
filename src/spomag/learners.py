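"""Training and tuning of the four supervised base algorithms.

All four algorithms are tuned inside a stratified 10-fold cross-validation
loop with area under the ROC curve as the selection metric:

* random forest — 500 trees, ``mtry`` (features tried per split) in {2, 3, 4};
* RBF-kernel SVM — cost grid C in {0.25, ..., 128}, kernel coefficient held
  at sigma = 0.0378 under the convention K(x, z) = exp(−sigma·||x − z||²);
* XGBoost — eta 0.1, depth 6, subsample/colsample 0.8, at most 100 rounds
  with early stopping (patience 10) on an internal validation carve-out;
* single-hidden-layer MLP — width tuned over a small grid by repeated CV,
  at most 200 optimizer iterations.

Ties in mean CV AUC are broken toward the simpler model (smaller mtry, C or
hidden width).  All randomness flows from the seed in :class:`CVConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._utils import derive_seed
from .features import FeatureMatrix

RF_MTRY_GRID = (2, 3, 4)
RF_N_TREES = 500
SVM_C_GRID = (0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, 128)
SVM_SIGMA = 0.0378  # K(x,z) = exp(-sigma * ||x-z||^2); sklearn's `gamma`
XGB_PARAMS = dict(learning_rate=0.1, max_depth=6, subsample=0.8,
                  colsample_bytree=0.8)
XGB_MAX_ROUNDS = 100
XGB_PATIENCE = 10
MLP_HIDDEN_GRID = (1, 3, 5, 7, 9)
MLP_MAX_ITER = 200
MLP_CV_REPEATS = 3

ALGORITHMS = ("rf", "svm_rbf", "xgboost", "mlp")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings; AUC is the fixed selection metric."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    selection_metric: str = "auc"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.selection_metric != "auc":
            raise ValueError("selection metric is fixed to AUC")


@dataclass
class TunedModel:
    """A tuned, refit estimator plus its CV bookkeeping.

    ``oof_proba`` holds the out-of-fold positive-class probability for every
    training row, produced by the winning hyperparameter setting during
    tuning (each row scored by a fold model that never saw it).
    """

    algorithm: str
    best_params: dict[str, Any]
    cv_auc: float
    fitted: Any
    seed: int
    oof_proba: np.ndarray | None = field(default=None, repr=False)

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        proba = self.fitted.predict_proba(np.asarray(X, dtype=np.float32))
        classes = list(self.fitted.classes_)
        return proba[:, classes.index(1)]


def stratified_partition(
    labels: dict[str, str] | Sequence[tuple[str, str]],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of labeled genome ids.

    Per class the training count is ``ceil(train_fraction × class size)``;
    the test set is the complement.  Deterministic given the seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    items = list(labels.items()) if isinstance(labels, dict) else list(labels)
    classes: dict[str, list[str]] = {}
    for gid, lab in items:
        classes.setdefault(lab, []).append(gid)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {sorted(classes)}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in sorted(classes):
        ids = sorted(classes[lab])
        if len(ids) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 members")
        n_train = int(np.ceil(train_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return sorted(train), sorted(test)


def _make_folds(
    y: np.ndarray, cv: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds whose training parts contain both classes."""
    for attempt in range(10):
        skf = StratifiedKFold(
            n_splits=cv.n_folds, shuffle=True,
            random_state=derive_seed(cv.seed, f"folds:{attempt}"),
        )
        folds = list(skf.split(np.zeros((len(y), 1)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not draw stratified folds with both classes")


def _xy(train: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(train.values, dtype=np.float32)
    y = train.label_array()
    return X, y


def _fold_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(y_true)) < 2:
        return np.nan
    return roc_auc_score(y_true, scores)


def _grid_cv_select(
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    candidates: Sequence[Any],
    fit_predict,  # (candidate, X_tr, y_tr, X_val, seed) -> scores
) -> tuple[Any, float, np.ndarray]:
    """Score each candidate over shared folds; return winner, its mean AUC,
    and its per-row out-of-fold scores.  Ties go to the earlier candidate."""
    folds = _make_folds(y, cv)
    best: tuple[int, float] | None = None
    oof_by_cand = []
    for ci, cand in enumerate(candidates):
        oof = np.full(len(y), np.nan)
        aucs = []
        for fi, (tr, val) in enumerate(folds):
            scores = fit_predict(
                cand, X[tr], y[tr], X[val],
                derive_seed(cv.seed, f"cand{ci}:fold{fi}"),
            )
            oof[val] = scores
            aucs.append(_fold_auc(y[val], scores))
        mean_auc = float(np.nanmean(aucs))
        oof_by_cand.append(oof)
        if best is None or mean_auc > best[1] + 1e-12:
            best = (ci, mean_auc)
    ci, auc = best
    return candidates[ci], auc, oof_by_cand[ci]


# ---------------------------------------------------------------------------
# per-algorithm constructors and tuners

def _build_rf(mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=RF_N_TREES, max_features=mtry, random_state=seed,
        n_jobs=1,
    )


def tune_random_forest(train: FeatureMatrix, cv: CVConfig) -> TunedModel:
    X, y = _xy(train)

    def fit_predict(mtry, X_tr, y_tr, X_val, seed):
        m = _build_rf(mtry, seed).fit(X_tr, y_tr)
        return m.predict_proba(X_val)[:, list(m.classes_).index(1)]

    best_mtry, auc, oof = _grid_cv_select(X, y, cv, RF_MTRY_GRID, fit_predict)
    final = _build_rf(best_mtry, derive_seed(cv.seed, "rf:final")).fit(X, y)
    return TunedModel(
        algorithm="rf",
        best_params={"mtry": best_mtry, "n_trees": RF_N_TREES},
        cv_auc=auc, fitted=final, seed=cv.seed, oof_proba=oof,
    )


def _build_svm(C: float, seed: int, probability: bool):
    svc = SVC(C=C, kernel="rbf", gamma=SVM_SIGMA, random_state=seed)
    if not probability:
        return svc
    # Platt-type sigmoid calibration fit on internal CV folds of the
    # training data; ensemble=False refits the SVC on all rows afterwards.
    return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)


def tune_svm_rbf(train: FeatureMatrix, cv: CVConfig) -> TunedModel:
    X, y = _xy(train)

    # Grid search scores folds with the decision function (rank-identical
    # to calibrated probabilities for AUC, far cheaper).
    def fit_predict(C, X_tr, y_tr, X_val, seed):
        return _build_svm(C, seed, probability=False).fit(X_tr, y_tr) \
            .decision_function(X_val)

    best_C, auc, _ = _grid_cv_select(X, y, cv, SVM_C_GRID, fit_predict)

    # Out-of-fold probabilities need the Platt-calibrated model.
    def fit_predict_proba(C, X_tr, y_tr, X_val, seed):
        m = _build_svm(C, seed, probability=True).fit(X_tr, y_tr)
        return m.predict_proba(X_val)[:, list(m.classes_).index(1)]

    _, _, oof = _grid_cv_select(X, y, cv, [best_C], fit_predict_proba)
    final = _build_svm(best_C, derive_seed(cv.seed, "svm:final"),
                       probability=True).fit(X, y)
    return TunedModel(
        algorithm="svm_rbf",
        best_params={"C": best_C, "sigma": SVM_SIGMA},
        cv_auc=auc, fitted=final, seed=cv.seed, oof_proba=oof,
    )


def _fit_xgb(X_tr, y_tr, seed) -> XGBClassifier:
    """Fit XGBoost with early stopping on an internal stratified carve-out."""
    X_fit, X_es, y_fit, y_es = train_test_split(
        X_tr, y_tr, test_size=0.2, stratify=y_tr, random_state=seed % (2**31),
    )
    m = XGBClassifier(
        n_estimators=XGB_MAX_ROUNDS, early_stopping_rounds=XGB_PATIENCE,
        eval_metric="auc", random_state=seed % (2**31), tree_method="hist",
        **XGB_PARAMS,
    )
    m.fit(X_fit, y_fit, eval_set=[(X_es, y_es)], verbose=False)
    return m


def tune_xgboost(train: FeatureMatrix, cv: CVConfig) -> TunedModel:
    X, y = _xy(train)

    def fit_predict(_, X_tr, y_tr, X_val, seed):
        m = _fit_xgb(X_tr, y_tr, seed)
        return m.predict_proba(X_val)[:, list(m.classes_).index(1)]

    _, auc, oof = _grid_cv_select(X, y, cv, ["fixed"], fit_predict)
    final = _fit_xgb(X, y, derive_seed(cv.seed, "xgb:final"))
    rounds_used = int(final.best_iteration) + 1
    return TunedModel(
        algorithm="xgboost",
        best_params={**XGB_PARAMS, "max_rounds": XGB_MAX_ROUNDS,
                     "patience": XGB_PATIENCE, "rounds_used": rounds_used},
        cv_auc=auc, fitted=final, seed=cv.seed, oof_proba=oof,
    )


def _build_mlp(width: int, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(width,), max_iter=MLP_MAX_ITER, solver="lbfgs",
        random_state=seed % (2**31),
    )


def tune_mlp(
    train: FeatureMatrix,
    cv: CVConfig,
    hidden_grid: Sequence[int] = MLP_HIDDEN_GRID,
    n_repeats: int = MLP_CV_REPEATS,
) -> TunedModel:
    X, y = _xy(train)

    def fit_predict(width, X_tr, y_tr, X_val, seed):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence at the 200-iter cap
            m = _build_mlp(width, seed).fit(X_tr, y_tr)
        return m.predict_proba(X_val)[:, list(m.classes_).index(1)]

    # Repeated CV: average each width's mean AUC over fold redraws.
    per_width = np.zeros(len(hidden_grid))
    oof_first: list[np.ndarray] = []
    for rep in range(n_repeats):
        rep_cv = CVConfig(n_folds=cv.n_folds, seed=derive_seed(cv.seed, f"mlp:rep{rep}"))
        folds = _make_folds(y, rep_cv)
        for wi, width in enumerate(hidden_grid):
            oof = np.full(len(y), np.nan)
            aucs = []
            for fi, (tr, val) in enumerate(folds):
                scores = fit_predict(
                    width, X[tr], y[tr], X[val],
                    derive_seed(cv.seed, f"mlp:rep{rep}:w{width}:f{fi}"),
                )
                oof[val] = scores
                aucs.append(_fold_auc(y[val], scores))
            per_width[wi] += float(np.nanmean(aucs)) / n_repeats
            if rep == 0:
                oof_first.append(oof)
    best_i = int(np.argmax(per_width > per_width.max() - 1e-12))
    best_width = hidden_grid[best_i]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = _build_mlp(best_width, derive_seed(cv.seed, "mlp:final")).fit(X, y)
    return TunedModel(
        algorithm="mlp",
        best_params={"hidden_width": best_width, "max_iter": MLP_MAX_ITER},
        cv_auc=float(per_width[best_i]), fitted=final, seed=cv.seed,
        oof_proba=oof_first[best_i],
    )


_TUNERS = {
    "rf": tune_random_forest,
    "svm_rbf": tune_svm_rbf,
    "xgboost": tune_xgboost,
    "mlp": tune_mlp,
}


def tune(algorithm: str, train: FeatureMatrix, cv: CVConfig) -> TunedModel:
    """Dispatch to the tuner for one of ``rf, svm_rbf, xgboost, mlp``."""
    if algorithm not in _TUNERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; one of {ALGORITHMS}")
    return _TUNERS[algorithm](train, cv)


def oof_probabilities(
    algorithm: str, train: FeatureMatrix, cv: CVConfig,
    params: dict[str, Any] | None = None,
) -> np.ndarray:
    """Leakage-free per-row probability of Sporulating.

    Every training genome is scored by a model fit on the other folds only.
    ``params`` fixes the hyperparameters (e.g. the tuned ones); defaults are
    the middle of each grid.
    """
    X, y = _xy(train)
    params = params or {}

    def fit_predict(_, X_tr, y_tr, X_val, seed):
        if algorithm == "rf":
            m = _build_rf(params.get("mtry", 3), seed).fit(X_tr, y_tr)
        elif algorithm == "svm_rbf":
            m = _build_svm(params.get("C", 1.0), seed, probability=True).fit(X_tr, y_tr)
        elif algorithm == "xgboost":
            m = _fit_xgb(X_tr, y_tr, seed)
        elif algorithm == "mlp":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _build_mlp(params.get("hidden_width", 5), seed).fit(X_tr, y_tr)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        return m.predict_proba(X_val)[:, list(m.classes_).index(1)]

    _, _, oof = _grid_cv_select(X, y, cv, ["fixed"], fit_predict)
    return oof
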