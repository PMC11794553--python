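import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from paleoiso.catchment import (
    CatchmentClusterer,
    SiteRecord,
    build_feature_matrix,
    cluster_composition,
    extract_catchment,
    kmeans_cluster,
    pca_reduce,
    select_k,
)
from paleoiso.raster import RasterGrid


def uniform_raster(value, shape=(60, 60), cell=150.0):
    return RasterGrid(values=np.full(shape, float(value)), cell_size=cell)


def center_site(grid):
    r = c = grid.shape[0] // 2
    x, y = grid.cell_center(r, c)
    return SiteRecord(site_id="S1", x=x, y=y)


class TestExtractCatchment:
    def test_uniform_rasters_give_constant_vector(self):
        g = uniform_raster(3.5)
        feats = extract_catchment(center_site(g), [g], radius=3000.0)
        assert (feats.vector == 3.5).all()

    def test_in_radius_cell_count_matches_brute_force(self):
        g = uniform_raster(1.0)
        feats = extract_catchment(center_site(g), [g], radius=3000.0)
        # enumerate window cell centres within 3000 m of the central cell
        half = feats.window_shape[0] // 2
        count = sum(
            1
            for dr in range(-half, half + 1)
            for dc in range(-half, half + 1)
            if np.hypot(dr, dc) * 150.0 <= 3000.0
        )
        assert feats.vector.size == count
        assert feats.mask.sum() == count

    def test_corner_site_raises_by_default(self):
        g = uniform_raster(1.0)
        x, y = g.cell_center(0, 0)
        site = SiteRecord(site_id="corner", x=x, y=y)
        with pytest.raises(ValueError, match="radius"):
            extract_catchment(site, [g], radius=3000.0)

    def test_corner_site_zero_pads_when_asked(self):
        g = uniform_raster(2.0)
        x, y = g.cell_center(0, 0)
        site = SiteRecord(site_id="corner", x=x, y=y)
        feats = extract_catchment(site, [g], radius=3000.0, edge_policy="pad")
        assert (feats.vector == 0).sum() > 0

    def test_soil_one_hot_expansion(self):
        soil = uniform_raster(40)
        feats = extract_catchment(
            center_site(soil), [soil], radius=600.0, soil_index=0
        )
        n_cells = feats.mask.sum()
        assert feats.vector.size == n_cells * 9
        assert feats.vector.sum() == n_cells  # exactly one hot per cell

    def test_vectors_identical_length_across_sites(self):
        g = uniform_raster(1.0)
        sites = pd.DataFrame(
            [
                {"site_id": "A", "x": 30 * 150.0, "y": -30 * 150.0},
                {"site_id": "B", "x": 25 * 150.0, "y": -25 * 150.0},
            ]
        )
        matrix, ids = build_feature_matrix(sites, [g], radius=3000.0)
        assert matrix.shape[0] == 2 and ids == ["A", "B"]


class TestPCA:
    def test_rank_one_matrix_keeps_single_component(self):
        u = np.arange(6, dtype=float)[:, None]
        X = u @ np.ones((1, 8))
        scores = pca_reduce(X)
        assert scores.shape == (6, 1)

    def test_cumulative_variance_vs_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 10))
        scores = pca_reduce(X, variance_kept=0.99)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        ratios = eigvals / eigvals.sum()
        n_expected = int(np.searchsorted(np.cumsum(ratios), 0.99) + 1)
        assert scores.shape[1] == n_expected
        assert np.cumsum(ratios)[scores.shape[1] - 1] >= 0.99

    def test_constant_columns_dropped_without_effect(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 5))
        Xpad = np.hstack([X, np.full((12, 3), 7.0)])
        np.testing.assert_allclose(
            np.abs(pca_reduce(X)), np.abs(pca_reduce(Xpad)), atol=1e-9
        )

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.ones((1, 4)))


def blobs(n_per=10, k=3, sep=20.0, seed=0, dim=2):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(k, dim))
    X = np.vstack([c + rng.normal(size=(n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestKMeans:
    def test_recovers_separated_blobs(self):
        X, truth = blobs()
        result = kmeans_cluster(X, k=3, seed=0)
        assert adjusted_rand_score(truth, result.assignments["cluster"]) == 1.0

    def test_k_equal_n_gives_zero_inertia(self):
        X, _ = blobs(n_per=2, k=2)
        result = kmeans_cluster(X, k=4, seed=0)
        assert result.inertia == pytest.approx(0.0, abs=1e-9)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.ones((3, 2)), k=4)

    def test_duplicated_points_cluster_like_originals(self):
        X, _ = blobs(seed=2)
        base = kmeans_cluster(X, k=3, seed=0).assignments["cluster"].to_numpy()
        dup = kmeans_cluster(np.vstack([X, X]), k=3, seed=0).assignments["cluster"].to_numpy()
        assert adjusted_rand_score(base, dup[: len(X)]) == 1.0
        assert (dup[: len(X)] == dup[len(X):]).all()

    def test_deterministic_under_seed(self):
        X, _ = blobs(seed=3)
        a = kmeans_cluster(X, k=3, seed=5).assignments
        b = kmeans_cluster(X, k=3, seed=5).assignments
        pd.testing.assert_frame_equal(a, b)


class TestSelectK:
    def test_silhouette_maximised_at_three_blobs(self):
        X, _ = blobs()
        diag = select_k(X, k_max=6, method="silhouette", B=10, seed=0)
        assert diag["silhouette_k"] == 3

    def test_gap_firstsemax_finds_three_blobs(self):
        X, _ = blobs(seed=1)
        diag = select_k(X, k_max=6, method="gap", B=30, seed=0)
        assert diag["gap_k"] == 3

    def test_uniform_data_recommends_small_k(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(40, 2))
        diag = select_k(X, k_max=8, method="gap", B=30, seed=0)
        assert diag["gap_k"] <= 3

    def test_kmax_one_degenerate_with_warning(self):
        X, _ = blobs()
        with pytest.warns(UserWarning):
            diag = select_k(X, k_max=1, B=5, seed=0)
        assert diag["recommended_k"] == 1

    def test_kmax_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.ones((5, 2)), k_max=5)


class TestComposition:
    def make_sites(self, n):
        return pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(n)],
                "region": ["A"] * (n // 2) + ["T"] * (n - n // 2),
                "period": ["EN", "MN"] * (n // 2),
                "culture": ["k"] * n,
            }
        )

    def test_single_cluster_one_row(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        result = kmeans_cluster(X, k=1, site_ids=[f"S{i}" for i in range(6)])
        tables = cluster_composition(result, self.make_sites(6))
        assert tables["region"].shape[0] == 1
        assert tables["region"].to_numpy().sum() == 6

    def test_counts_conserved_in_every_table(self):
        X, _ = blobs(n_per=4, k=3)
        result = kmeans_cluster(X, k=3, site_ids=[f"S{i}" for i in range(12)])
        tables = cluster_composition(result, self.make_sites(12))
        for table in tables.values():
            assert table.to_numpy().sum() == 12


class TestCatchmentClusterer:
    def test_sklearn_estimator_contract(self):
        est = CatchmentClusterer(k=3, B=5)
        params = est.get_params()
        assert params["k"] == 3
        est.set_params(k=2)
        assert est.k == 2

    def test_fit_exposes_fitted_attributes(self):
        X, truth = blobs()
        est = CatchmentClusterer(k=3, random_state=0).fit(X)
        assert est.k_ == 3
        assert est.labels_.min() >= 1 and est.labels_.max() <= 3
        assert adjusted_rand_score(truth, est.labels_) == 1.0
        assert np.isfinite(est.inertia_)

    def test_auto_k_selects_three_blobs(self):
        X, truth = blobs(seed=5)
        est = CatchmentClusterer(k="auto", selection="silhouette", k_max=6, B=10, random_state=0)
        labels = est.fit_predict(X)
        assert est.k_ == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_predict_assigns_training_points_consistently(self):
        X, _ = blobs(seed=6)
        est = CatchmentClusterer(k=3, random_state=0).fit(X)
        np.testing.assert_array_equal(est.predict(X), est.labels_)

    def test_feature_permutation_invariance(self):
        X, _ = blobs(seed=7, dim=4)
        perm = [2, 0, 3, 1]
        a = CatchmentClusterer(k=3, random_state=0).fit(X).labels_
        b = CatchmentClusterer(k=3, random_state=0).fit(X[:, perm]).labels_
        assert adjusted_rand_score(a, b) == 1.0
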