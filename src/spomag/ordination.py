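"""Ordination and multivariate dispersion of presence/absence profiles.

Binary (Jaccard) distances between genomes, centered PCA of the 0/1 matrix,
and a homogeneity-of-dispersion analysis in the style of ``betadisper``:
the distance matrix is embedded by principal-coordinates analysis (double
centering of squared distances, keeping axes with negative eigenvalues),
each genome's distance to its phenotype-group centroid is computed with the
imaginary-axis correction d² = d²(real axes) − d²(imaginary axes), and
group differences in mean dispersion are tested with a one-way ANOVA F
statistic whose null distribution comes from label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import FeatureMatrix


@dataclass
class BinaryDistanceMatrix:
    """Symmetric pairwise binary distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n},{n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def binary_distance(matrix: FeatureMatrix) -> BinaryDistanceMatrix:
    """Jaccard distance between genome presence/absence profiles.

    d(i, j) = (# positions where exactly one genome has the gene) /
    (# positions where at least one has it); two all-absent genomes are at
    distance 0 by convention.
    """
    X = matrix.values.astype(np.float64)
    inter = X @ X.T
    sums = X.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    xor = sums[:, None] + sums[None, :] - 2 * inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, xor / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return BinaryDistanceMatrix(ids=list(matrix.genome_ids), values=d)


@dataclass
class PCAResult:
    """Centered PCA of the binary matrix."""

    scores: pd.DataFrame      # genomes × components
    loadings: pd.DataFrame    # genes × components
    percent_variance: np.ndarray


def pca_presence_absence(matrix: FeatureMatrix) -> PCAResult:
    """PCA of the centered (not scaled) 0/1 matrix.

    Component signs follow a fixed convention: the largest-magnitude
    loading of each component is made positive.
    """
    if matrix.n_genomes < 2:
        raise ValueError("PCA needs at least two genomes")
    X = matrix.values.astype(np.float64)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(matrix.n_genomes - 1, matrix.n_genes)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    keep = s > 1e-12 * max(s[0], 1.0)  # drop zero-variance components
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    n_comp = int(keep.sum())
    for k in range(n_comp):  # deterministic sign convention
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * s
    var = s**2
    pct = 100 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.genome_ids, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=matrix.gene_symbols, columns=comp_names),
        percent_variance=pct,
    )


@dataclass
class DispersionResult:
    """Distance-to-centroid dispersion with a permutation ANOVA p-value."""

    distances: pd.Series          # per genome, non-negative
    group_means: dict[str, float]
    f_statistic: float
    p_value: float | None = None
    n_permutations: int = 0


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F over integer-coded groups (closed form)."""
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        vals = values[codes == g]
        ss_between += len(vals) * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def betadispersion(
    dist: BinaryDistanceMatrix, groups: dict[str, str]
) -> DispersionResult:
    """Per-genome distance to its group centroid in PCoA space.

    Axes with negative eigenvalues (imaginary axes of a non-Euclidean
    distance) contribute negatively: d² = d²(real) − d²(imaginary), floored
    at zero before taking the square root.
    """
    ids = dist.ids
    labels = np.array([groups[g] for g in ids])
    uniq = sorted(set(labels))
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    D = dist.values
    n = len(ids)
    # PCoA: double-center -0.5 * D^2.
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    eigval, eigvec = np.linalg.eigh(G)
    keep = np.abs(eigval) > 1e-10 * max(1.0, np.abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))[None, :]
    positive = eigval > 0
    distances = np.empty(n)
    for g in uniq:
        members = labels == g
        centroid = coords[members].mean(axis=0)
        delta2 = (coords[members] - centroid) ** 2
        d2 = delta2[:, positive].sum(axis=1) - delta2[:, ~positive].sum(axis=1)
        distances[members] = np.sqrt(np.maximum(d2, 0.0))
    codes = np.searchsorted(np.array(uniq), labels)
    f = _anova_f(distances, codes, len(uniq))
    return DispersionResult(
        distances=pd.Series(distances, index=ids, name="dist_to_centroid"),
        group_means={g: float(distances[labels == g].mean()) for g in uniq},
        f_statistic=float(f),
    )


def permutation_anova(
    result: DispersionResult,
    groups: dict[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> DispersionResult:
    """Permutation p-value for the dispersion F statistic.

    Group labels are permuted over the fixed distance-to-centroid vector;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values = result.distances.to_numpy()
    labels = np.array([groups[g] for g in result.distances.index])
    uniq = sorted(set(labels))
    codes = np.searchsorted(np.array(uniq), labels)
    rng = np.random.default_rng(seed)
    f_obs = result.f_statistic
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _anova_f(values, perm, len(uniq)) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return replace(result, p_value=p, n_permutations=n_permutations)
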