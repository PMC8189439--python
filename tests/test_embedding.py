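import numpy as np
import pandas as pd
import pytest

from embryostage.embedding import (
    average_linkage_order,
    joint_pca,
    kde_evaluate,
    loading_density,
    normal_reference_bandwidth,
    run_pca,
)
from embryostage.matrix import ExpressionMatrix, GeneSet, StageReference


def _matrix(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        "log2fpkm",
    )


def _pca_eig_oracle(X, k):
    """Independent PCA via dense eigendecomposition of the covariance."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    loadings = v[:, order]
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return Xc @ loadings, loadings


class TestRunPca:
    def test_duplicated_sample_scores_coincide(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(3, 1, size=(30, 5))
        arr = np.column_stack([arr, arr[:, 2]])
        emb = run_pca(_matrix(arr), n_components=3)
        np.testing.assert_allclose(
            emb.sample_scores.loc["s2"], emb.sample_scores.loc["s5"], atol=1e-10
        )

    def test_two_samples_single_component(self):
        arr = np.random.default_rng(1).normal(0, 1, size=(20, 2))
        emb = run_pca(_matrix(arr), n_components=1)
        assert emb.explained_variance[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(0, 1, size=(20, 6))
            emb = run_pca(_matrix(X.T), n_components=4)
            scores_o, loadings_o = _pca_eig_oracle(X, 4)
            np.testing.assert_allclose(
                emb.sample_scores.to_numpy(), scores_o, atol=1e-8
            )
            np.testing.assert_allclose(
                emb.gene_loadings.to_numpy(), loadings_o, atol=1e-8
            )

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(8, 15))  # 8 samples x 15 genes
        emb = run_pca(_matrix(X.T), n_components=7)
        centered = X - X.mean(axis=0)
        recon = emb.sample_scores.to_numpy() @ emb.gene_loadings.to_numpy().T
        err = np.linalg.norm(recon - centered) / np.linalg.norm(centered)
        assert err <= 1e-6

    def test_loadings_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(4)
        emb = run_pca(_matrix(rng.normal(0, 1, (40, 10))), n_components=5)
        L = emb.gene_loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-10)
        ev = emb.explained_variance
        assert (np.diff(ev) <= 1e-12).all() and ev.sum() <= 1 + 1e-9

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(0, 1, (30, 6))
        m = _matrix(arr)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        m2 = ExpressionMatrix(m.values[perm], "log2fpkm")
        a = run_pca(m, 3).sample_scores
        b = run_pca(m2, 3).sample_scores
        np.testing.assert_allclose(a.loc[perm].to_numpy(), b.to_numpy(), atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            run_pca(_matrix(np.ones((5, 3)) + np.eye(5, 3)), n_components=4)


class TestJointPca:
    def _ref(self, arr):
        return StageReference(
            pd.DataFrame(np.asarray(arr, float),
                         index=[f"g{i}" for i in range(len(arr))],
                         columns=["stA", "stB", "stC"]),
            "log2fpkm",
        )

    def test_query_equal_to_stage_is_coincident(self):
        rng = np.random.default_rng(6)
        base = rng.normal(3, 1, size=(30, 3))
        ref = self._ref(base)
        query = ExpressionMatrix(
            pd.DataFrame(base[:, [1]], index=ref.gene_ids, columns=["q1"]),
            "log2fpkm",
        )
        emb = joint_pca(query, ref, n_components=2)
        np.testing.assert_allclose(
            emb.sample_scores.loc["q1"], emb.sample_scores.loc["stB"], atol=1e-10
        )
        assert emb.sample_labels["q1"] == "query"
        assert emb.sample_labels["stB"] == "reference"

    def test_small_overlap_rejected(self):
        ref = self._ref(np.random.default_rng(0).normal(0, 1, (30, 3)))
        query = _matrix(np.random.default_rng(1).normal(0, 1, (30, 4)))
        gs = GeneSet("few", tuple(ref.gene_ids[:5]))
        with pytest.raises(ValueError, match="shared"):
            joint_pca(query, ref, gene_filter=gs)

    def test_te_branch_sample_lands_near_te_stage(self, sim_bundle):
        _, ref, tc, meta, truth = sim_bundle
        final = [s for s in tc.sample_ids if s.startswith("TE_d5_")]
        query = ExpressionMatrix(tc.values[final], tc.scale)
        emb = joint_pca(query, ref, n_components=2)
        coords = emb.sample_scores
        for q in final:
            dists = {
                s: np.linalg.norm(coords.loc[q] - coords.loc[s])
                for s in ref.stages
            }
            assert min(dists, key=dists.get) in ("eTE", "lTE")


class TestLoadingDensity:
    def test_single_point_peak_at_gene(self):
        rng = np.random.default_rng(7)
        emb = run_pca(_matrix(rng.normal(0, 1, (50, 6))), n_components=2)
        pair = GeneSet("pair", ("g0", "g1"))
        grid = loading_density(emb, pair, bandwidth=(0.05, 0.05), gridsize=(200, 200))
        peak = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        peak_xy = np.array([grid.x[peak[0]], grid.y[peak[1]]])
        pts = emb.gene_loadings.loc[["g0", "g1"], ["PC1", "PC2"]].to_numpy()
        assert min(np.linalg.norm(peak_xy - p) for p in pts) < 0.05

    def test_mass_close_to_one(self):
        rng = np.random.default_rng(8)
        emb = run_pca(_matrix(rng.normal(0, 1, (200, 8))), n_components=2)
        gs = GeneSet("all", tuple(emb.gene_loadings.index))
        grid = loading_density(emb, gs, gridsize=(128, 128))
        assert grid.mass() == pytest.approx(1.0, abs=0.05)
        assert (grid.density >= 0).all()

    def test_kde_matches_analytic_bivariate_normal(self):
        rng = np.random.default_rng(42)
        pts = rng.multivariate_normal([0, 0], np.eye(2), size=500)
        h = normal_reference_bandwidth(pts)
        est = kde_evaluate(np.array([0.0, 0.0]), pts, h)[0]
        analytic = 1.0 / (2 * np.pi)
        assert est == pytest.approx(analytic, rel=0.15)

    def test_levels_are_point_density_quantiles(self):
        rng = np.random.default_rng(9)
        emb = run_pca(_matrix(rng.normal(0, 1, (100, 6))), n_components=2)
        gs = GeneSet("all", tuple(emb.gene_loadings.index))
        grid = loading_density(emb, gs, level_quantiles=(0.5,))
        assert grid.levels.shape == (1,)
        assert grid.levels[0] > 0

    def test_all_genes_missing_rejected(self):
        rng = np.random.default_rng(10)
        emb = run_pca(_matrix(rng.normal(0, 1, (20, 4))), n_components=2)
        with pytest.raises(ValueError, match="need >= 2"):
            loading_density(emb, GeneSet("none", ("x1", "x2")))


def _upgma_oracle(X):
    """Quadratic reference UPGMA returning merge heights."""
    clusters = {i: [i] for i in range(len(X))}
    dist = {(i, j): np.linalg.norm(X[i] - X[j])
            for i in range(len(X)) for j in range(i + 1, len(X))}
    heights = []
    next_id = len(X)
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        members = clusters.pop(a) + clusters.pop(b)
        for c in list(clusters):
            pair_ab = tuple(sorted((a, c)))
            pair_bb = tuple(sorted((b, c)))
            na, nb = len(clusters[c]), 0  # unused; average over point pairs below
            d = np.mean([np.linalg.norm(X[i] - X[j])
                         for i in members for j in clusters[c]])
            dist[tuple(sorted((next_id, c)))] = d
            dist.pop(pair_ab, None)
            dist.pop(pair_bb, None)
        dist.pop(tuple(sorted((a, b))), None)
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        clusters[next_id] = members
        next_id += 1
    return np.array(heights)


class TestAverageLinkageOrder:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(0, 1, (6, 4))
        arr[4] = arr[1]
        order = average_linkage_order(_matrix(arr), axis="genes")
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos[1] - pos[4]) == 1

    def test_line_points_merge_near_pair_first(self):
        arr = np.array([[0.0, 0], [1.0, 0], [10.0, 0]])
        order = average_linkage_order(_matrix(arr), axis="genes")
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos[0] - pos[1]) == 1  # 0 and 1 merge first

    def test_merge_heights_match_brute_force_oracle(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, size=(8, 4))
        Z = hierarchy.linkage(pdist(X), method="average")
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(_upgma_oracle(X)),
                                   atol=1e-10)
        # and the packaged function returns a permutation of all leaves
        order = average_linkage_order(_matrix(X), axis="genes")
        assert sorted(order) == list(range(8))
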