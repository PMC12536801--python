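"""The SpoMAG stacked-generalization ensemble.

Random-forest and RBF-SVM base learners are tuned on the training matrix;
their *out-of-fold* probabilities (each training genome scored only by fold
models that never saw it) form a two-column meta-feature table on which a
small random-forest meta-classifier (mtry in {1, 2}) is tuned by 10-fold
CV AUC.  For deployment both bases are refit on the full training set, and
a new genome's probability of sporulating is the meta forest's probability
over the two base probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import __version__
from ._utils import NEGATIVE_LABEL, POSITIVE_LABEL, derive_seed, sha256_file
from .features import FeatureMatrix
from .learners import (
    CVConfig,
    TunedModel,
    _grid_cv_select,
    _xy,
    tune_random_forest,
    tune_svm_rbf,
)

META_MTRY_GRID = (1, 2)
META_N_TREES = 500


class BundleError(RuntimeError):
    """Model-bundle integrity or compatibility failure."""


@dataclass
class EnsembleBundle:
    """Fitted SpoMAG ensemble: two base learners plus the meta forest."""

    rf_base: TunedModel
    svm_base: TunedModel
    meta: RandomForestClassifier
    meta_mtry: int
    meta_cv_auc: float
    decision_threshold: float = 0.5
    catalog_checksum: str = ""
    seed: int = 0
    manifest: dict[str, Any] = field(default_factory=dict)


def train_spomag(train: FeatureMatrix, cv: CVConfig) -> EnsembleBundle:
    """Tune bases, build leakage-free meta-features, tune the meta forest."""
    rf = tune_random_forest(train, cv)
    svm = tune_svm_rbf(train, cv)
    meta_X = np.column_stack([rf.oof_proba, svm.oof_proba]).astype(np.float32)
    assert not np.isnan(meta_X).any(), "out-of-fold probabilities incomplete"
    y = train.label_array()

    def fit_predict(mtry, X_tr, y_tr, X_val, seed):
        m = RandomForestClassifier(
            n_estimators=META_N_TREES, max_features=mtry,
            random_state=seed, n_jobs=1,
        ).fit(X_tr, y_tr)
        return m.predict_proba(X_val)[:, list(m.classes_).index(1)]

    meta_cv = CVConfig(n_folds=cv.n_folds, seed=derive_seed(cv.seed, "meta"))
    best_mtry, meta_auc, _ = _grid_cv_select(
        meta_X, y, meta_cv, META_MTRY_GRID, fit_predict
    )
    meta = RandomForestClassifier(
        n_estimators=META_N_TREES, max_features=best_mtry,
        random_state=derive_seed(cv.seed, "meta:final"), n_jobs=1,
    ).fit(meta_X, y)
    manifest = {
        "tool": "spomag",
        "version": __version__,
        "seed": cv.seed,
        "n_folds": cv.n_folds,
        "n_train_genomes": train.n_genomes,
        "catalog_checksum": train.catalog_checksum,
        "decision_threshold": 0.5,
        "rf": {"cv_auc": rf.cv_auc, **rf.best_params},
        "svm_rbf": {"cv_auc": svm.cv_auc, **svm.best_params},
        "meta": {"mtry": best_mtry, "n_trees": META_N_TREES,
                 "cv_auc": meta_auc},
    }
    return EnsembleBundle(
        rf_base=rf, svm_base=svm, meta=meta, meta_mtry=best_mtry,
        meta_cv_auc=meta_auc, catalog_checksum=train.catalog_checksum,
        seed=cv.seed, manifest=manifest,
    )


def _check_alignment(bundle: EnsembleBundle, matrix: FeatureMatrix) -> None:
    if bundle.catalog_checksum and matrix.catalog_checksum and \
            bundle.catalog_checksum != matrix.catalog_checksum:
        raise BundleError(
            "feature matrix catalog checksum "
            f"{matrix.catalog_checksum!r} does not match the bundle's "
            f"{bundle.catalog_checksum!r}; re-run align_matrix with the "
            "bundle's catalog"
        )


def base_probabilities(
    bundle: EnsembleBundle, matrix: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(matrix.values, dtype=np.float32)
    return (bundle.rf_base.predict_proba_positive(X),
            bundle.svm_base.predict_proba_positive(X))


def predict_proba(bundle: EnsembleBundle, matrix: FeatureMatrix) -> np.ndarray:
    """Per-genome probability of the Sporulating phenotype."""
    _check_alignment(bundle, matrix)
    rf_p, svm_p = base_probabilities(bundle, matrix)
    meta_X = np.column_stack([rf_p, svm_p]).astype(np.float32)
    proba = bundle.meta.predict_proba(meta_X)
    return proba[:, list(bundle.meta.classes_).index(1)]


def predict_table(bundle: EnsembleBundle, matrix: FeatureMatrix) -> pd.DataFrame:
    """Prediction report: probabilities, label calls and gene counts.

    A genome is called Sporulating when its ensemble probability is >= the
    bundle's decision threshold (default 0.5).
    """
    _check_alignment(bundle, matrix)
    rf_p, svm_p = base_probabilities(bundle, matrix)
    meta_X = np.column_stack([rf_p, svm_p]).astype(np.float32)
    prob = bundle.meta.predict_proba(meta_X)[
        :, list(bundle.meta.classes_).index(1)
    ]
    df = pd.DataFrame(
        {
            "genome_id": matrix.genome_ids,
            "prob_sporulating": prob,
            "rf_prob": rf_p,
            "svm_prob": svm_p,
            "predicted_label": np.where(
                prob >= bundle.decision_threshold, POSITIVE_LABEL, NEGATIVE_LABEL
            ),
            "n_genes_present": matrix.values.sum(axis=1).astype(int),
        }
    )
    return df.sort_values("genome_id", kind="stable").reset_index(drop=True)


_MODEL_FILES = ("rf_base.joblib", "svm_base.joblib", "meta.joblib")


def save_bundle(bundle: EnsembleBundle, directory: str | Path) -> None:
    """Serialize the bundle: three model files plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.rf_base, directory / "rf_base.joblib")
    joblib.dump(bundle.svm_base, directory / "svm_base.joblib")
    joblib.dump(bundle.meta, directory / "meta.joblib")
    manifest = dict(bundle.manifest)
    manifest.update(
        {
            "decision_threshold": bundle.decision_threshold,
            "catalog_checksum": bundle.catalog_checksum,
            "meta_mtry": bundle.meta_mtry,
            "meta_cv_auc": bundle.meta_cv_auc,
            "seed": bundle.seed,
            "model_checksums": {
                name: sha256_file(directory / name) for name in _MODEL_FILES
            },
        }
    )
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_bundle(directory: str | Path) -> EnsembleBundle:
    """Load a bundle, verifying file checksums and version compatibility."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"missing manifest: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    major = str(manifest.get("version", "")).split(".")[0]
    if major != __version__.split(".")[0]:
        raise BundleError(
            f"bundle written by spomag {manifest.get('version')!r}; "
            f"this is {__version__} (incompatible major version)"
        )
    for name in _MODEL_FILES:
        path = directory / name
        if not path.exists():
            raise BundleError(f"missing model file: {path}")
        expected = manifest.get("model_checksums", {}).get(name)
        if expected and sha256_file(path) != expected:
            raise BundleError(f"checksum mismatch for {name}; bundle corrupted")
    rf = joblib.load(directory / "rf_base.joblib")
    svm = joblib.load(directory / "svm_base.joblib")
    meta = joblib.load(directory / "meta.joblib")
    return EnsembleBundle(
        rf_base=rf, svm_base=svm, meta=meta,
        meta_mtry=int(manifest["meta_mtry"]),
        meta_cv_auc=float(manifest["meta_cv_auc"]),
        decision_threshold=float(manifest["decision_threshold"]),
        catalog_checksum=manifest.get("catalog_checksum", ""),
        seed=int(manifest.get("seed", 0)),
        manifest=manifest,
    )
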