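"""Performance metrics, bootstrap confidence intervals, model comparison.

Six metrics are reported throughout: accuracy, AUC, recall (sensitivity for
the Sporulating class), specificity, precision, and F1.  Uncertainty comes
from a non-parametric bootstrap: the training set is resampled with
replacement (stratified, preserving class counts), the model is retrained on
each resample, and the metrics are recomputed on a fixed, untouched test
set; medians and percentile 95% confidence intervals summarize the 300
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._utils import derive_seed, log
from .features import FeatureMatrix
from .learners import CVConfig, tune
from .stacking import predict_proba, train_spomag

METRIC_NAMES = ("accuracy", "auc", "recall", "specificity", "precision", "f1")

#: A trainer maps (training matrix, seed) -> predictor; a predictor maps a
#: FeatureMatrix -> per-genome probability of Sporulating.
Predictor = Callable[[FeatureMatrix], np.ndarray]
Trainer = Callable[[FeatureMatrix, int], Predictor]


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion table; positive class = Sporulating."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: float | None = None
    auc: float | None = None
    recall: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Threshold metrics from a confusion table (AUC left undefined)."""
    if counts.total <= 0:
        raise ValueError("empty confusion table")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(
        accuracy=(counts.tp + counts.tn) / counts.total,
        auc=None,
        recall=recall,
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        precision=precision,
        f1=f1,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = Mann–Whitney concordance probability, ties counted one-half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_scores(
    proba: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """All six metrics from probabilities and 0/1 labels."""
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    pred = (proba >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    )
    base = confusion_metrics(counts)
    auc = roc_auc(proba, labels) if len(np.unique(labels)) == 2 else None
    return MetricSet(**{**base.as_dict(), "auc": auc})


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-metric median and percentile 95% CI over bootstrap iterations."""

    median: dict[str, float | None]
    ci_low: dict[str, float | None]
    ci_high: dict[str, float | None]
    n_iterations: int
    n_undefined: dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median": self.median,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        ).loc[list(METRIC_NAMES)]


def _stratified_resample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Row indices of a with-replacement resample preserving class counts."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_evaluate(
    train: FeatureMatrix,
    test: FeatureMatrix,
    trainer: Trainer,
    n_iter: int = 300,
    seed: int = 0,
    threshold: float = 0.5,
) -> BootstrapSummary:
    """Retrain on stratified bootstrap resamples, evaluate on the fixed test.

    The test set never enters a resample.  Undefined metric values (e.g.
    precision with no positive call) are dropped from the summaries with a
    logged count.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if set(train.genome_ids) & set(test.genome_ids):
        raise ValueError("train and test sets overlap")
    y_train = train.label_array()
    y_test = test.label_array()
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    n_undef = {m: 0 for m in METRIC_NAMES}
    for it in range(n_iter):
        for _ in range(20):  # guard against a degenerate resample
            rows = _stratified_resample(y_train, rng)
            if len(np.unique(y_train[rows])) == 2:
                break
        resample = _subset_with_replacement(train, rows)
        predictor = trainer(resample, derive_seed(seed, f"boot:{it}"))
        metrics = evaluate_scores(predictor(test), y_test, threshold=threshold)
        for m, v in metrics.as_dict().items():
            if v is None:
                n_undef[m] += 1
            else:
                samples[m].append(v)
    median, lo, hi = {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array(samples[m])
        if vals.size == 0:
            median[m] = lo[m] = hi[m] = None
            continue
        median[m] = float(np.median(vals))
        lo[m] = float(np.percentile(vals, 2.5))
        hi[m] = float(np.percentile(vals, 97.5))
        if n_undef[m]:
            log.warning("metric %s undefined in %d/%d iterations",
                        m, n_undef[m], n_iter)
    return BootstrapSummary(
        median=median, ci_low=lo, ci_high=hi,
        n_iterations=n_iter, n_undefined=n_undef,
    )


def _subset_with_replacement(
    matrix: FeatureMatrix, rows: np.ndarray
) -> FeatureMatrix:
    """Subset allowing repeated rows (bootstrap); ids are made unique."""
    ids = []
    seen: dict[str, int] = {}
    for i in rows:
        gid = matrix.genome_ids[i]
        k = seen.get(gid, 0)
        seen[gid] = k + 1
        ids.append(gid if k == 0 else f"{gid}__b{k}")
    labels = None
    if matrix.labels:
        labels = {
            new: matrix.labels[matrix.genome_ids[i]]
            for new, i in zip(ids, rows)
        }
    return FeatureMatrix(
        genome_ids=ids,
        gene_symbols=list(matrix.gene_symbols),
        values=matrix.values[rows],
        labels=labels,
        catalog_checksum=matrix.catalog_checksum,
    )


# ---------------------------------------------------------------------------
# five-model comparison report

def _single_model_trainer(algorithm: str, cv: CVConfig) -> Trainer:
    def trainer(train: FeatureMatrix, seed: int) -> Predictor:
        model = tune(algorithm, train, CVConfig(n_folds=cv.n_folds, seed=seed))
        return lambda m: model.predict_proba_positive(m.values)
    return trainer


def spomag_trainer(cv: CVConfig) -> Trainer:
    def trainer(train: FeatureMatrix, seed: int) -> Predictor:
        bundle = train_spomag(train, CVConfig(n_folds=cv.n_folds, seed=seed))
        return lambda m: predict_proba(bundle, m)
    return trainer


def format_metric_cell(
    median: float | None, lo: float | None, hi: float | None
) -> str:
    """``87.5 (77.5–97.5)`` percentage formatting, trailing .0 stripped."""
    if median is None:
        return ""

    def pct(v: float) -> str:
        s = f"{100 * v:.1f}"
        return s[:-2] if s.endswith(".0") else s

    return f"{pct(median)} ({pct(lo)}–{pct(hi)})"


def compare_models(
    matrix: FeatureMatrix,
    cv: CVConfig,
    n_iter: int = 300,
    seed: int = 0,
    train_fraction: float = 0.7,
    models: tuple[str, ...] = ("rf", "svm_rbf", "xgboost", "mlp", "spomag"),
) -> tuple[pd.DataFrame, dict]:
    """Five-model comparison on one stratified 70/30 split.

    Returns the formatted report table (models × six metrics, each cell
    ``median (ci_low–ci_high)`` in percent) and a machine-readable dict of
    raw floats.
    """
    from .learners import stratified_partition  # local to avoid cycle noise

    train_ids, test_ids = stratified_partition(
        matrix.labels, train_fraction, derive_seed(seed, "split")
    )
    train, test = matrix.subset(train_ids), matrix.subset(test_ids)
    rows: dict[str, dict[str, str]] = {}
    raw: dict[str, dict] = {"n_iterations": n_iter, "models": {}}
    for name in models:
        trainer = (
            spomag_trainer(cv) if name == "spomag"
            else _single_model_trainer(name, cv)
        )
        summary = bootstrap_evaluate(
            train, test, trainer, n_iter=n_iter,
            seed=derive_seed(seed, f"boot:{name}"),
        )
        rows[name] = {
            m: format_metric_cell(
                summary.median[m], summary.ci_low[m], summary.ci_high[m]
            )
            for m in METRIC_NAMES
        }
        raw["models"][name] = {
            "median": summary.median,
            "ci_low": summary.ci_low,
            "ci_high": summary.ci_high,
        }
    report = pd.DataFrame(rows).T.loc[list(models), list(METRIC_NAMES)]
    report.index.name = "model"
    return report, raw
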