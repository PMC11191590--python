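"""Variance-targeted PCA, seeded embedding, silhouette gating and keyword subsetting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from addscreen.cluster_pipeline import (
    GridSpec,
    embed,
    grid_search_clustering,
    reduce_pca,
    silhouette_score,
    subset_cancer_keywords,
)

TINY_GRID = GridSpec(n_neighbors=(10,), min_dist=(0.1,), k_range=(3, 4, 5), seeds=(0,))


def blob_matrix(seed=0, n_per=20, centers=((0, 0, 0), (40, 0, 0), (0, 40, 0))):
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for c, center in enumerate(centers):
        rows.append(rng.normal(loc=center, scale=0.5, size=(n_per, len(center))))
        truth += [c] * n_per
    X = np.vstack(rows)
    idx = [f"chem{i}" for i in range(len(X))]
    # pad with low-variance extra columns so PCA has something to discard
    extra = rng.normal(scale=0.01, size=(len(X), 3))
    return pd.DataFrame(np.hstack([X, extra]), index=idx), np.array(truth)


class TestReducePca:
    def test_rank_one_keeps_one_component(self):
        v = np.arange(10.0)
        X = pd.DataFrame(np.outer(v, [1, 2, 3]))
        assert reduce_pca(X).shape[1] == 1

    def test_equal_variances_keep_all(self):
        # four zero-mean orthogonal axes with identical variance (Hadamard
        # columns): no subset reaches 95%, so all four components are kept
        from scipy.linalg import hadamard

        X = pd.DataFrame(hadamard(8)[:, 1:5].astype(float) * 10)
        red = reduce_pca(X)
        assert red.shape[1] == 4

    def test_variance_target_met(self):
        X, _ = blob_matrix()
        red = reduce_pca(X, 0.95)
        assert red.attrs["explained_variance_ratio"].sum() >= 0.95

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError):
            reduce_pca(pd.DataFrame(np.ones((5, 3))))


class TestEmbed:
    def test_fixed_seed_deterministic(self):
        X, _ = blob_matrix()
        a = embed(X, 10, 0.1, 2, seed=3)
        b = embed(X, 10, 0.1, 2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_output_dimensionality(self):
        X, _ = blob_matrix()
        assert embed(X, 10, 0.1, 2, 0).shape == (len(X), 2)

    def test_blob_separation_preserved(self):
        X, truth = blob_matrix(centers=((0, 0), (50, 0)))
        emb = embed(X, 10, 0.1, 2, 0).to_numpy()
        a, b = emb[truth == 0], emb[truth == 1]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = max(
            np.mean([np.linalg.norm(p - q) for p in grp for q in grp])
            for grp in (a, b)
        )
        assert between > within

    def test_too_few_rows_errors(self):
        X, _ = blob_matrix(n_per=3, centers=((0, 0),))
        with pytest.raises(ValueError):
            embed(X, 10, 0.1, 2, 0)


class TestSilhouette:
    def test_two_tight_pairs(self):
        # {0, 0.1} vs {10, 10.1}: a=0.1 everywhere; b=10.05 / 9.95 per side
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = [0, 0, 1, 1]
        s0 = (10.05 - 0.1) / 10.05
        s1 = (9.95 - 0.1) / 9.95
        expected = (2 * s0 + 2 * s1) / 4
        assert silhouette_score(pts, labels) == pytest.approx(expected, abs=1e-12)
        assert silhouette_score(pts, labels) == pytest.approx(0.99, abs=1e-4)

    def test_interleaved_identical_points_nonpositive(self):
        pts = np.array([[0.0], [0.0], [0.0], [0.0]])
        assert silhouette_score(pts, [0, 1, 0, 1]) <= 0

    def test_bounded(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        s = silhouette_score(pts, rng.integers(0, 3, size=30))
        assert -1.0 <= s <= 1.0

    def test_label_permutation_invariant(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 2))
        labels = rng.integers(0, 3, size=20)
        permuted = (labels + 1) % 3
        assert silhouette_score(pts, labels) == pytest.approx(
            silhouette_score(pts, permuted)
        )

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            silhouette_score(np.zeros((4, 1)), [0, 0, 0, 0])


class TestGridSearch:
    def test_recovers_planted_blobs(self):
        X, truth = blob_matrix()
        result = grid_search_clustering(X, TINY_GRID)
        assert result.accepted
        assert result.best.k == 3
        assert adjusted_rand_score(truth, result.best.labels) == 1.0

    def test_uniform_noise_below_floor(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(size=(60, 8)))
        result = grid_search_clustering(X, TINY_GRID)
        assert not result.accepted
        assert result.best is not None  # failure report still carries the best

    def test_rerun_identical(self):
        X, _ = blob_matrix()
        a = grid_search_clustering(X, TINY_GRID)
        b = grid_search_clustering(X, TINY_GRID)
        assert a.best.params == b.best.params
        assert a.best.silhouette == b.best.silhouette
        pd.testing.assert_series_equal(a.best.labels, b.best.labels)

    def test_row_order_invariant_up_to_relabeling(self):
        X, truth = blob_matrix()
        perm = np.random.default_rng(9).permutation(len(X))
        result_a = grid_search_clustering(X, TINY_GRID)
        result_b = grid_search_clustering(X.iloc[perm], TINY_GRID)
        la = result_a.best.labels.reindex(X.index)
        lb = result_b.best.labels.reindex(X.index)
        assert adjusted_rand_score(la, lb) == 1.0

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            grid_search_clustering(pd.DataFrame(), TINY_GRID)


class TestKeywordSubset:
    def make(self):
        mat = pd.DataFrame(
            [[1.0, 0.0, 2.0], [0.0, 3.0, 0.0], [0.0, 0.0, 0.0]],
            index=["a", "b", "c"],
            columns=["S1", "S2", "S3"],
        )
        names = {
            "S1": "Prostate Cancer_K",
            "S2": "Fatty acid beta-oxidation",
            "S3": "Hepatocellular Carcinoma",
        }
        return mat, names

    def test_keyword_columns_retained(self):
        mat, names = self.make()
        sub, kept = subset_cancer_keywords(mat, names)
        assert list(sub.columns) == ["S1", "S3"]  # carcinoma matches "carcin"
        assert kept == ["a"]  # only row with a nonzero retained cell

    def test_no_match_warns_and_empties(self):
        mat, _ = self.make()
        with pytest.warns(UserWarning):
            sub, kept = subset_cancer_keywords(mat, {"S1": "x", "S2": "y", "S3": "z"})
        assert sub.empty and kept == []

    def test_column_labels_used_without_names(self):
        mat, _ = self.make()
        mat = mat.rename(columns={"S1": "tumor suppression"})
        sub, _ = subset_cancer_keywords(mat)
        assert list(sub.columns) == ["tumor suppression"]


class TestFullRecovery:
    def test_planted_clusters_recovered(self, strong_dataset, strong_er, strong_solution):
        """The full pipeline on the strong-signal fixture finds the planted
        three-cluster partition above the silhouette floor."""
        assert strong_solution.accepted
        assert strong_solution.best.k == 3
        truth = [strong_dataset.truth.cluster_of[c] for c in strong_er.index]
        assert adjusted_rand_score(truth, strong_solution.best.labels) >= 0.9

    def test_keyword_subset_preserves_cluster_count(self, strong_dataset, strong_er, strong_solution):
        """Clustering only the cancer-keyword pathways finds the same number
        of clusters as the full matrix (signature pathways carry keywords)."""
        from conftest import REDUCED_GRID

        from addscreen.cluster_pipeline import cluster_er_matrix

        names = {gs.set_id: gs.name for gs in strong_dataset.gene_sets}
        sub, kept = subset_cancer_keywords(strong_er, names)
        assert len(kept) > 0
        result = cluster_er_matrix(sub, REDUCED_GRID)
        assert result.accepted
        assert result.best.k == strong_solution.best.k
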