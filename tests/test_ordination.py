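import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spomag import (
    betadispersion,
    binary_distance,
    pca_presence_absence,
    permutation_anova,
)
from spomag.ordination import BinaryDistanceMatrix, _anova_f
from .conftest import make_matrix


def brute_force_jaccard(u, v):
    informative = [(a, b) for a, b in zip(u, v) if a or b]
    if not informative:
        return 0.0
    discordant = sum(1 for a, b in informative if a != b)
    return discordant / len(informative)


class TestBinaryDistance:
    def test_worked_example(self):
        m = make_matrix(np.array([[1, 0, 1], [1, 1, 0]]))
        d = binary_distance(m)
        assert d.values[0, 1] == pytest.approx(2 / 3)

    def test_identical_and_all_zero_conventions(self):
        m = make_matrix(np.array([[1, 0, 1], [1, 0, 1], [0, 0, 0], [0, 0, 0]]))
        d = binary_distance(m).values
        assert d[0, 1] == 0.0
        assert d[2, 3] == 0.0  # no informative positions → 0 by convention
        assert d[0, 2] == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(arrays(np.uint8,
                  st.tuples(st.integers(2, 8), st.integers(1, 10)),
                  elements=st.integers(0, 1)))
    def test_any_binary_matrix_matches_brute_force(self, X):
        d = binary_distance(make_matrix(X)).values
        n = X.shape[0]
        for i in range(n):
            for j in range(n):
                assert d[i, j] == pytest.approx(
                    brute_force_jaccard(X[i], X[j]))

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, (10, 12))
        d = binary_distance(make_matrix(X)).values
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    brute_force_jaccard(X[i], X[j])
                )
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestPCA:
    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(0)
        res = pca_presence_absence(make_matrix(rng.integers(0, 2, (12, 8))))
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_distinct_genomes_single_component(self):
        res = pca_presence_absence(make_matrix(np.array([[1, 0, 0], [0, 1, 1]])))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_constant_column_gets_zero_loading(self):
        X = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
        res = pca_presence_absence(make_matrix(X))
        assert np.allclose(res.loadings.loc["f000"], 0.0, atol=1e-12)

    def test_row_order_invariance_with_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (9, 7))
        m = make_matrix(X)
        res1 = pca_presence_absence(m)
        rev = m.subset(list(reversed(m.genome_ids)))
        res2 = pca_presence_absence(rev)
        a = res1.scores.loc[m.genome_ids].to_numpy()
        b = res2.scores.loc[m.genome_ids].to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError, match="two genomes"):
            pca_presence_absence(make_matrix(np.array([[1, 0]])))


def _euclidean_dist_matrix(points):
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


class TestBetadispersion:
    def test_euclidean_toy_matches_direct_centroid_geometry(self):
        # 6 points in the plane, two groups of 3; PCoA of Euclidean
        # distances must reproduce plain centroid distances.
        pts = np.array([[0.0, 0], [2, 0], [1, 2], [5, 5], [6, 5], [5.5, 7]])
        ids = [f"g{i}" for i in range(6)]
        groups = {g: ("A" if i < 3 else "B") for i, g in enumerate(ids)}
        dist = BinaryDistanceMatrix(ids, _euclidean_dist_matrix(pts) / 10)
        res = betadispersion(dist, groups)
        for grp, sel in (("A", slice(0, 3)), ("B", slice(3, 6))):
            centroid = pts[sel].mean(axis=0)
            direct = np.sqrt(((pts[sel] - centroid) ** 2).sum(axis=1)) / 10
            assert np.allclose(res.distances.iloc[sel], direct, atol=1e-9)

    def test_copied_point_clouds_equal_dispersion(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 2, (5, 10))
        X = np.vstack([block, block])
        m = make_matrix(X)
        groups = {g: ("A" if i < 5 else "B")
                  for i, g in enumerate(m.genome_ids)}
        res = betadispersion(binary_distance(m), groups)
        assert res.group_means["A"] == pytest.approx(res.group_means["B"])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-18)

    def test_identical_points_zero_distances(self):
        X = np.tile(np.array([[1, 0, 1, 0]]), (6, 1))
        m = make_matrix(X)
        groups = {g: ("A" if i < 3 else "B")
                  for i, g in enumerate(m.genome_ids)}
        res = betadispersion(binary_distance(m), groups)
        assert np.allclose(res.distances, 0.0)

    def test_small_group_rejected(self):
        m = make_matrix(np.eye(3, dtype=np.uint8))
        groups = dict(zip(m.genome_ids, ["A", "A", "B"]))
        with pytest.raises(ValueError, match="fewer than 2"):
            betadispersion(binary_distance(m), groups)

    def test_f_invariant_to_label_swap(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.integers(0, 2, (10, 8)))
        g1 = {g: ("A" if i < 5 else "B") for i, g in enumerate(m.genome_ids)}
        g2 = {g: ("B" if i < 5 else "A") for i, g in enumerate(m.genome_ids)}
        d = binary_distance(m)
        assert betadispersion(d, g1).f_statistic == pytest.approx(
            betadispersion(d, g2).f_statistic
        )

    def test_matches_vegan_betadisper(self, tmp_path):
        """Independent oracle: vegan::betadisper on a small binary matrix."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript unavailable")
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (12, 15))
        m = make_matrix(X)
        groups = {g: ("A" if i < 6 else "B")
                  for i, g in enumerate(m.genome_ids)}
        res = betadispersion(binary_distance(m), groups)
        np.savetxt(tmp_path / "X.tsv", X, fmt="%d", delimiter="\t")
        rcode = f"""
        X <- as.matrix(read.table("{tmp_path}/X.tsv"))
        g <- factor(rep(c("A","B"), each=6))
        suppressMessages(library(vegan))
        bd <- betadisper(dist(X, method="binary"), g, type="centroid")
        cat(anova(bd)$"F value"[1], bd$distances, sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        values = [float(v) for v in out.stdout.split()]
        assert res.f_statistic == pytest.approx(values[0], rel=1e-5)
        assert np.allclose(res.distances.to_numpy(), values[1:], atol=1e-6)


class TestPermutationAnova:
    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(4)
        block = rng.integers(0, 2, (6, 12))
        m = make_matrix(np.vstack([block, block]))
        groups = {g: ("A" if i < 6 else "B")
                  for i, g in enumerate(m.genome_ids)}
        res = permutation_anova(
            betadispersion(binary_distance(m), groups), groups,
            n_permutations=199, seed=0,
        )
        assert res.p_value > 0.05

    def test_p_value_formula(self):
        # manual count: F_obs forced to 0 so every permutation is >= it
        rng = np.random.default_rng(5)
        m = make_matrix(rng.integers(0, 2, (8, 6)))
        groups = {g: ("A" if i < 4 else "B")
                  for i, g in enumerate(m.genome_ids)}
        res = betadispersion(binary_distance(m), groups)
        res.f_statistic = 0.0
        out = permutation_anova(res, groups, n_permutations=99, seed=1)
        assert out.p_value == pytest.approx(1.0)
        assert out.n_permutations == 99

    def test_anova_f_matches_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(6)
        vals = rng.random(14)
        codes = np.array([0] * 7 + [1] * 7)
        ours = _anova_f(vals, codes, 2)
        ref = f_oneway(vals[:7], vals[7:]).statistic
        assert ours == pytest.approx(ref)
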