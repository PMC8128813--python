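import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import habitatmap as hm
from habitatmap.core import HabitatError


def stack_from_matrix(X, hu=None):
    """Wrap an (n, 9) feature matrix as a TextureMapStack on a 1-slice grid."""
    n = X.shape[0]
    feats = np.zeros((9, 1, 1, n))
    feats[:, 0, 0, :] = X.T
    hu = np.zeros(n) if hu is None else np.asarray(hu, float)
    return hm.TextureMapStack(
        features=feats,
        hu=hu.reshape(1, 1, n),
        valid=np.ones((1, 1, n), dtype=bool),
    )


class TestComponentSelection:
    @pytest.mark.parametrize(
        "ratios,target,cap,expected",
        [
            ((0.5, 0.3, 0.15, 0.05), 0.90, 6, 3),
            ((0.5, 0.3, 0.15, 0.05), 0.96, 6, 4),
            ((0.3, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05, 0.05), 0.90, 6, 6),
            ((0.95, 0.05), 0.90, 6, 1),
        ],
    )
    def test_cumulative_rule(self, ratios, target, cap, expected):
        assert hm.select_component_count(ratios, target, cap) == expected


class TestFitPCA:
    def test_rank_two_data_gives_two_components(self, rng):
        u = rng.standard_normal(9)
        v = rng.standard_normal(9)
        coef = rng.standard_normal((200, 2))
        X = coef[:, :1] * u + coef[:, 1:] * v
        model = hm.fit_pca([stack_from_matrix(X)])
        assert model.m == 2
        assert model.cumulative_explained == pytest.approx(1.0, abs=1e-9)

    def test_explained_matches_eigendecomposition_oracle(self, small_phantom):
        stack = hm.texture_map_stack(small_phantom.volume, small_phantom.mask)
        model = hm.fit_pca([stack])
        X = stack.feature_matrix()
        scale = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        Z = (X - X.mean(axis=0)) / scale
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        ratios = eigvals / eigvals.sum()
        np.testing.assert_allclose(model.explained, ratios[: model.m], atol=1e-8)
        assert np.cumsum(ratios)[model.m - 1] >= 0.90 or model.capped

    def test_loadings_orthonormal(self, small_phantom):
        stack = hm.texture_map_stack(small_phantom.volume, small_phantom.mask)
        model = hm.fit_pca([stack])
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(model.m), atol=1e-10
        )

    def test_insufficient_training_data(self, rng):
        X = rng.standard_normal((30, 9))
        with pytest.raises(HabitatError, match="insufficient training data"):
            hm.fit_pca([stack_from_matrix(X)])

    def test_zero_variance_feature_warns(self, rng):
        X = rng.standard_normal((200, 9))
        X[:, 4] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            hm.fit_pca([stack_from_matrix(X)])

    def test_json_round_trip(self, small_phantom, tmp_path):
        stack = hm.texture_map_stack(small_phantom.volume, small_phantom.mask)
        model = hm.fit_pca([stack])
        model.to_json(tmp_path / "pca.json")
        back = hm.PCAModel.from_json(tmp_path / "pca.json")
        np.testing.assert_array_equal(back.loadings, model.loadings)
        np.testing.assert_array_equal(back.mean, model.mean)
        assert back.m == model.m


class TestProject:
    def test_reconstruction_error_bounded_by_unexplained_variance(
        self, small_phantom
    ):
        stack = hm.texture_map_stack(small_phantom.volume, small_phantom.mask)
        model = hm.fit_pca([stack])
        X = stack.feature_matrix()
        Z = (X - model.mean) / model.scale
        pcs = hm.project(stack, model)
        recon = pcs @ model.loadings.T
        rel_err = np.sum((Z - recon) ** 2) / np.sum((Z - Z.mean(axis=0)) ** 2)
        assert rel_err <= 1.0 - model.cumulative_explained + 1e-6

    def test_training_mean_projects_to_zero(self, small_phantom):
        stack = hm.texture_map_stack(small_phantom.volume, small_phantom.mask)
        model = hm.fit_pca([stack])
        np.testing.assert_allclose(
            model.transform(model.mean[None, :]), 0.0, atol=1e-10
        )


class TestFitHabitats:
    def test_single_gaussian_selects_one_component(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pcs = rng.standard_normal((2000, 2))
            hu = 50.0 + 10.0 * rng.standard_normal(2000)
            model = hm.fit_habitats(pcs, hu, hm.PipelineConfig(seed=seed))
            assert model.k == min(model.aic_by_k, key=model.aic_by_k.get)
            hits += model.k == 1
        assert hits >= 9

    def test_two_well_separated_gaussians_recovered(self):
        rng = np.random.default_rng(5)
        half = 1000
        pcs = np.vstack(
            [rng.standard_normal((half, 2)), rng.standard_normal((half, 2)) + 10.0]
        )
        hu = np.concatenate(
            [40 + rng.standard_normal(half), 90 + rng.standard_normal(half)]
        )
        truth = np.repeat([0, 1], half)
        model = hm.fit_habitats(pcs, hu, hm.PipelineConfig(seed=5))
        assert model.k == 2
        mask = hm.VOIMask(np.ones((1, 1, 2 * half), bool), (1, 1, 2 * half))
        hmap, _ = hm.label_habitats(model, pcs, hu, mask)
        assert adjusted_rand_score(truth, hmap.labels.ravel()) >= 0.99

    def test_k_never_exceeds_cap(self, rng):
        pcs = rng.standard_normal((500, 3)) ** 3  # heavy-tailed on purpose
        hu = rng.standard_normal(500) * 30
        model = hm.fit_habitats(pcs, hu, hm.PipelineConfig(seed=0))
        assert 1 <= model.k <= 3
        assert set(model.aic_by_k) <= {1, 2, 3}

    def test_too_few_voxels_rejected(self, rng):
        with pytest.raises(HabitatError, match="too few voxels"):
            hm.fit_habitats(rng.standard_normal((20, 2)),
                            rng.standard_normal(20), hm.PipelineConfig())


class TestLabelHabitats:
    def test_single_component_labels_everything_one(self, rng):
        pcs = rng.standard_normal((200, 2))
        hu = 40 + rng.standard_normal(200)
        cfg = hm.PipelineConfig(seed=1, k_max=1)
        model = hm.fit_habitats(pcs, hu, cfg)
        mask = hm.VOIMask(np.ones((1, 1, 200), bool), (1, 1, 200))
        hmap, post = hm.label_habitats(model, pcs, hu, mask, config=cfg)
        assert hmap.k == 1 and np.all(hmap.labels == 1)
        assert post.shape == (200, 1)

    def test_labels_ordered_by_mean_hu(self):
        rng = np.random.default_rng(3)
        half = 500
        pcs = np.vstack(
            [rng.standard_normal((half, 2)), 8.0 + rng.standard_normal((half, 2))]
        )
        hu = np.concatenate(
            [120 + rng.standard_normal(half), 20 + rng.standard_normal(half)]
        )
        cfg = hm.PipelineConfig(seed=3, k_max=2)
        model = hm.fit_habitats(pcs, hu, cfg)
        assert model.k == 2
        mask = hm.VOIMask(np.ones((1, 1, 2 * half), bool), (1, 1, 2 * half))
        hmap, _ = hm.label_habitats(model, pcs, hu, mask, config=cfg)
        # label 1 must be the low-HU component
        assert hu[hmap.labels.ravel() == 1].mean() < hu[hmap.labels.ravel() == 2].mean()

    def test_same_seed_bit_identical(self, small_phantom):
        runs = []
        for _ in range(2):
            res = hm.compute_habitats(
                small_phantom.volume, small_phantom.mask,
                hm.PipelineConfig(seed=42),
            )
            runs.append(res.habitat_map)
        assert np.array_equal(runs[0].labels, runs[1].labels)
        np.testing.assert_array_equal(runs[0].volumes_cm3, runs[1].volumes_cm3)


class TestEnforceMinVolume:
    def _map_with_volumes(self, counts, spacing=(10.0, 10.0, 10.0)):
        """1D layout: first counts[0] voxels are label 1, etc."""
        n = sum(counts)
        labels = np.zeros((1, 1, n), dtype=np.int32)
        start = 0
        for lbl, c in enumerate(counts, start=1):
            labels[0, 0, start: start + c] = lbl
            start += c
        voxel_cm3 = float(np.prod(spacing)) / 1000.0
        hmap = hm.HabitatMap(labels=labels, k=len(counts),
                             volumes_cm3=np.array(counts) * voxel_cm3)
        return hmap, voxel_cm3

    def test_all_above_floor_unchanged(self):
        hmap, _ = self._map_with_volumes([10, 10, 10])  # 10 cm^3 each
        post = np.tile([0.5, 0.3, 0.2], (30, 1))
        out = hm.enforce_min_volume(hmap, post, 3.0, (10, 10, 10))
        assert np.array_equal(out.labels, hmap.labels)

    def test_small_habitat_dissolved_with_volume_conserved(self):
        hmap, voxel_cm3 = self._map_with_volumes([10, 10, 2])  # label 3: 2 cm^3
        post = np.zeros((22, 3))
        post[:, 0] = 0.2
        post[:, 1] = 0.7  # dissolved voxels should join label 2
        post[:, 2] = 0.1
        out = hm.enforce_min_volume(hmap, post, 3.0, (10, 10, 10))
        assert out.k == 2
        assert out.volumes_cm3.sum() == pytest.approx(
            hmap.volumes_cm3.sum(), abs=1e-9
        )
        assert out.volumes_cm3[1] == pytest.approx(12 * voxel_cm3)

    def test_single_habitat_never_dissolved(self):
        hmap, _ = self._map_with_volumes([2])  # below floor but k=1
        out = hm.enforce_min_volume(hmap, np.ones((2, 1)), 3.0, (10, 10, 10))
        assert out.k == 1 and np.all(out.labels == hmap.labels)

    def test_cascading_dissolution_stops_at_floor(self):
        hmap, _ = self._map_with_volumes([1, 1, 1])  # all 1 cm^3
        post = np.tile([0.4, 0.35, 0.25], (3, 1))
        out = hm.enforce_min_volume(hmap, post, 3.0, (10, 10, 10))
        assert out.k == 1
        assert out.volumes_cm3.sum() == pytest.approx(3.0)
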