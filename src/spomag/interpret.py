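"""Shapley-value attribution and gene-level interpretation.

Feature importance is attributed with Shapley values of the model's
Sporulating probability with respect to feature presence, estimated by
permutation sampling against a background (reference) set of genomes: for
each sampled (permutation, background genome) pair, features are switched
from the background value to the explained genome's value in permutation
order, and each feature is credited with the change in model output it
causes.  Antithetic permutation pairs (a permutation and its reverse) cut
the estimator's variance, and the same sample draws are shared across all
explained genomes, which makes the additivity identity

    base_value + sum_j phi_j = f(x)

hold exactly for every genome (the telescoping sums cancel).

The consensus rule mirrors the dual-model reading of importance: only genes
whose *mean signed* contribution is positive in both the random-forest and
the SVM base model are retained, ranked by the average of the two models'
mean absolute contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._utils import log
from .catalog import GeneCatalog
from .features import FeatureMatrix

#: A probability model to explain: maps an (n, d) float array to (n,) probs.
ProbModel = Callable[[np.ndarray], np.ndarray]


@dataclass
class ShapMatrix:
    """Per-genome, per-gene attributions toward the Sporulating probability."""

    genome_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray  # (n_genomes, n_genes)
    base_value: float
    n_samples: int
    model_tag: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.genome_ids, name="genome_id"),
            columns=self.gene_symbols,
        )


def shap_values(
    model: ProbModel,
    matrix: FeatureMatrix,
    background: FeatureMatrix,
    n_samples: int = 200,
    seed: int = 0,
    model_tag: str = "",
) -> ShapMatrix:
    """Permutation-sampling Shapley attribution of a probability model.

    ``n_samples`` is the number of (permutation, background-row) draws;
    below ``2 × n_features`` the estimate is noisy and a warning is logged.
    Deterministic given the seed.
    """
    X = np.asarray(matrix.values, dtype=np.float32)
    bg = np.asarray(background.values, dtype=np.float32)
    if bg.shape[0] == 0:
        raise ValueError("background matrix is empty")
    n, d = X.shape
    if n_samples < 2 * d:
        log.warning(
            "n_samples=%d < 2×%d features; Shapley estimates will be loose",
            n_samples, d,
        )
    rng = np.random.default_rng(seed)
    # Shared draws across genomes: antithetic permutation pairs + bg rows.
    n_pairs = (n_samples + 1) // 2
    perms = np.empty((2 * n_pairs, d), dtype=np.int64)
    for k in range(n_pairs):
        p = rng.permutation(d)
        perms[2 * k] = p
        perms[2 * k + 1] = p[::-1]
    perms = perms[:n_samples]
    bg_rows = bg[rng.integers(0, bg.shape[0], size=n_samples)]

    base_value = float(np.mean(model(bg_rows)))
    # mask[s, k, j] — feature j is among the first k entries of permutation s;
    # shared across genomes so every genome sees identical coalition draws.
    rank = np.empty_like(perms)
    np.put_along_axis(rank, perms, np.arange(d)[None, :], axis=1)
    mask = rank[:, None, :] < np.arange(d + 1)[None, :, None]
    values = np.zeros((n, d), dtype=np.float64)
    for gi in range(n):
        x = X[gi]
        # hybrids[s, k] = background row s with the first k features (in
        # permutation order) switched to x; k = 0..d.
        hybrids = np.where(mask, x[None, None, :], bg_rows[:, None, :])
        preds = model(hybrids.reshape(-1, d)).reshape(n_samples, d + 1)
        deltas = np.diff(preds, axis=1)  # (n_samples, d) in permutation order
        contrib = np.zeros(d)
        np.add.at(contrib, perms.ravel(), deltas.ravel())
        values[gi] = contrib / n_samples
    return ShapMatrix(
        genome_ids=list(matrix.genome_ids),
        gene_symbols=list(matrix.gene_symbols),
        values=values,
        base_value=base_value,
        n_samples=n_samples,
        model_tag=model_tag,
    )


def sklearn_prob_model(estimator) -> ProbModel:
    """Wrap a fitted sklearn-style classifier as a probability function."""
    pos = list(estimator.classes_).index(1)

    def f(X: np.ndarray) -> np.ndarray:
        return estimator.predict_proba(np.asarray(X, dtype=np.float32))[:, pos]

    return f


def mean_abs_shap(shap: ShapMatrix) -> pd.DataFrame:
    """Per-gene mean |attribution| and mean signed attribution.

    Sorted descending by mean absolute value.
    """
    if len(shap.genome_ids) == 0:
        raise ValueError("empty attribution matrix")
    df = pd.DataFrame(
        {
            "mean_abs_shap": np.abs(shap.values).mean(axis=0),
            "mean_signed_shap": shap.values.mean(axis=0),
        },
        index=pd.Index(shap.gene_symbols, name="gene_symbol"),
    )
    return df.sort_values("mean_abs_shap", ascending=False, kind="stable")


@dataclass
class ConsensusGenes:
    """Dual-model positive-consensus genes, most important first."""

    table: pd.DataFrame  # columns: mean_abs_shap_rf, mean_abs_shap_svm, ...
    rule_tag: str = "positive mean signed contribution in both base models"

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def consensus_positive_genes(
    shap_rf: ShapMatrix, shap_svm: ShapMatrix
) -> ConsensusGenes:
    """Genes with positive mean signed contribution in both base models,
    ranked by the average of the two mean-absolute attributions."""
    if shap_rf.gene_symbols != shap_svm.gene_symbols:
        raise ValueError("attribution matrices have different gene orders")
    rf_signed = shap_rf.values.mean(axis=0)
    svm_signed = shap_svm.values.mean(axis=0)
    rf_abs = np.abs(shap_rf.values).mean(axis=0)
    svm_abs = np.abs(shap_svm.values).mean(axis=0)
    keep = (rf_signed > 0) & (svm_signed > 0)
    df = pd.DataFrame(
        {
            "mean_abs_shap_rf": rf_abs[keep],
            "mean_abs_shap_svm": svm_abs[keep],
            "mean_signed_shap_rf": rf_signed[keep],
            "mean_signed_shap_svm": svm_signed[keep],
        },
        index=pd.Index(
            [g for g, k in zip(shap_rf.gene_symbols, keep) if k],
            name="gene_symbol",
        ),
    )
    df["rank_score"] = (df["mean_abs_shap_rf"] + df["mean_abs_shap_svm"]) / 2
    return ConsensusGenes(
        table=df.sort_values("rank_score", ascending=False, kind="stable")
    )


@dataclass
class CoreGeneReport:
    """Genes present in every genome of a predicted-sporulator set."""

    core_genes: list[str]
    presence_counts: pd.Series  # per gene: number of listed genomes carrying it
    stage_counts: pd.DataFrame | None  # genomes × stages gene-content counts


def core_genes(
    matrix: FeatureMatrix,
    predicted_sporulators: list[str],
    catalog: GeneCatalog | None = None,
) -> CoreGeneReport:
    """Core genes of a set of predicted spore-formers.

    Also reports, per gene, how many of the listed genomes carry it (the
    presence histogram) and, when a catalog is supplied, each genome's gene
    count per sporulation stage.
    """
    if not predicted_sporulators:
        raise ValueError("predicted_sporulators must be non-empty")
    sub = matrix.subset(list(predicted_sporulators))
    counts = pd.Series(
        sub.values.sum(axis=0).astype(int),
        index=pd.Index(sub.gene_symbols, name="gene_symbol"),
        name="n_present",
    )
    core = [g for g, c in counts.items() if c == sub.n_genomes]
    stage_counts = None
    if catalog is not None:
        stages = pd.Series(
            {e.gene_symbol: e.stage for e in catalog.entries}
        ).reindex(sub.gene_symbols)
        stage_counts = (
            sub.to_frame()
            .T.groupby(stages)
            .sum()
            .T.rename_axis(index="genome_id", columns="stage")
        )
    return CoreGeneReport(
        core_genes=core, presence_counts=counts, stage_counts=stage_counts
    )
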