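import numpy as np
import pytest

from sphereinsight.exceptions import DomainError, ValidationError
from sphereinsight.insight_imaging import (
    distinct_supports,
    feature_layout,
    min_area_rectangle,
    normalize_values,
    pixel_assignment,
    render_images,
    support_mask,
)


def _layout_from_coords(coords):
    from sphereinsight.insight_imaging import FeatureLayout

    coords = np.asarray(coords, dtype=float)
    return FeatureLayout(
        feature_ids=[f"f{i}" for i in range(coords.shape[0])],
        coords2d=coords, method="pca", seed=0,
    )


class TestFeatureLayout:
    def test_pca_recovers_planar_geometry(self, rng):
        # features on a 2D affine plane in 6D: PCA coordinates reproduce
        # pairwise distances up to rigid motion
        n_feat = 30
        latent = rng.normal(size=(n_feat, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        samples = (latent @ basis.T + 5.0).T  # 6 "samples" x 30 features
        layout = feature_layout(samples, method="pca", seed=0)
        d_latent = np.linalg.norm(latent[:, None] - latent[None], axis=-1)
        d_layout = np.linalg.norm(layout.coords2d[:, None] - layout.coords2d[None],
                                  axis=-1)
        np.testing.assert_allclose(d_layout, d_latent, atol=1e-8)

    @pytest.mark.parametrize("method", ["pca", "kpca", "tsne"])
    def test_deterministic_per_seed(self, rng, method):
        X = rng.normal(size=(20, 40))
        a = feature_layout(X, method=method, seed=7)
        b = feature_layout(X, method=method, seed=7)
        np.testing.assert_array_equal(a.coords2d, b.coords2d)

    def test_two_features_rejected(self, rng):
        with pytest.raises(ValidationError):
            feature_layout(rng.normal(size=(10, 2)), method="pca", seed=0)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValidationError, match="unknown"):
            feature_layout(rng.normal(size=(10, 5)), method="umap", seed=0)


def _sweep_oracle_area(pts, n_angles=3600):
    best = np.inf
    for ang in np.linspace(0, np.pi / 2, n_angles, endpoint=False):
        c, s = np.cos(ang), np.sin(ang)
        rot = pts @ np.array([[c, s], [-s, c]])
        area = np.prod(rot.max(axis=0) - rot.min(axis=0))
        best = min(best, area)
    return best


class TestMinAreaRectangle:
    def test_axis_aligned_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        angle, corners = min_area_rectangle(pts)
        assert angle % (np.pi / 2) == pytest.approx(0.0, abs=1e-12)
        area = np.linalg.norm(corners[1] - corners[0]) * \
            np.linalg.norm(corners[2] - corners[1])
        assert area == pytest.approx(1.0, abs=1e-12)

    def test_rotated_square_recovers_angle(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        t = np.deg2rad(30)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        angle, corners = min_area_rectangle(pts @ R.T)
        assert (angle - t) % (np.pi / 2) == pytest.approx(0.0, abs=1e-10) or \
            (t - angle) % (np.pi / 2) == pytest.approx(0.0, abs=1e-10)
        area = np.linalg.norm(corners[1] - corners[0]) * \
            np.linalg.norm(corners[2] - corners[1])
        assert area == pytest.approx(1.0, abs=1e-10)

    def test_matches_angle_sweep_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(50, 2))
            angle, corners = min_area_rectangle(pts)
            side_a = np.linalg.norm(corners[1] - corners[0])
            side_b = np.linalg.norm(corners[2] - corners[1])
            oracle = _sweep_oracle_area(pts)
            assert side_a * side_b <= oracle * 1.001

    def test_matches_shapely_oracle(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import MultiPoint

        pts = rng.normal(size=(40, 2))
        _, corners = min_area_rectangle(pts)
        mine = np.linalg.norm(corners[1] - corners[0]) * \
            np.linalg.norm(corners[2] - corners[1])
        ref = MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle.area
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_collinear_fallback(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        angle, corners = min_area_rectangle(pts)
        assert np.isfinite(angle)


class TestPixelAssignment:
    def test_corners_map_to_grid_corners(self):
        layout = _layout_from_coords([[0, 0], [0, 1], [1, 0], [1, 1]])
        pmap = pixel_assignment(layout, angle=0.0, grid_h=10, grid_w=10)
        pixels = {tuple(p) for p in pmap.pixel_of_feature}
        assert pixels == {(0, 0), (0, 9), (9, 0), (9, 9)}

    def test_identical_coordinates_collide(self):
        layout = _layout_from_coords([[0, 0], [0.5, 0.5], [0.5, 0.5], [1, 1]])
        pmap = pixel_assignment(layout, angle=0.0, grid_h=8, grid_w=8)
        sizes = sorted(len(g) for g in pmap.collision_groups.values())
        assert sizes == [1, 1, 2]

    def test_foreground_bounded_by_feature_count(self, rng):
        for _ in range(10):
            layout = _layout_from_coords(rng.normal(size=(37, 2)))
            pmap = pixel_assignment(layout, angle=0.3, grid_h=12, grid_w=12)
            assert pmap.foreground_mask.sum() <= 37
            assert sum(len(g) for g in pmap.collision_groups.values()) == 37

    def test_small_grid_rejected(self):
        layout = _layout_from_coords([[0, 0], [1, 1], [0, 1]])
        with pytest.raises(ValidationError):
            pixel_assignment(layout, angle=0.0, grid_h=1, grid_w=8)


class TestNormalizeValues:
    def test_independent_midpoint(self):
        X = np.array([[2.0], [6.0], [4.0]])
        out = normalize_values(X, "independent", train_index=np.array([0, 1]))
        np.testing.assert_allclose(out, [[0.0], [1.0], [0.5]])

    def test_constant_feature_maps_to_zero(self):
        X = np.full((4, 2), 3.0)
        assert normalize_values(X, "independent").max() == 0.0

    def test_independent_train_extremes_hit_bounds(self, rng):
        X = rng.normal(size=(30, 8))
        tr = np.arange(20)
        out = normalize_values(X, "independent", train_index=tr)
        np.testing.assert_allclose(out[tr].min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(out[tr].max(axis=0), 1.0, atol=1e-15)

    def test_topology_preserving_keeps_cross_cell_order(self, rng):
        X = rng.normal(size=(15, 6))
        out = normalize_values(X, "topology_preserving")
        flat_x, flat_o = X.ravel(), out.ravel()
        order = np.argsort(flat_x)
        assert np.all(np.diff(flat_o[order]) >= -1e-15)

    def test_test_values_clip_to_unit_interval(self, rng):
        X = rng.normal(size=(30, 5))
        X[25:] *= 10  # test rows far outside the train range
        out = normalize_values(X, "independent", train_index=np.arange(25))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_train_subset_rejected(self):
        with pytest.raises(ValidationError):
            normalize_values(np.ones((3, 2)), "independent",
                             train_index=np.array([], dtype=int))


class TestRenderImages:
    def _pmap(self):
        layout = _layout_from_coords([[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5]])
        return pixel_assignment(layout, angle=0.0, grid_h=6, grid_w=6)

    def test_all_zero_sample_segmented_is_constant_epsilon(self):
        pmap = self._pmap()
        X = np.zeros((1, 5))
        stack = render_images(X, pmap, epsilon=1 / 255, segment=True)
        fg = pmap.foreground_mask
        assert np.all(stack.images[0][fg] == 1 / 255)
        assert np.all(stack.images[0][~fg] == 0.0)

    def test_all_zero_sample_unsegmented_vanishes(self):
        pmap = self._pmap()
        stack = render_images(np.zeros((1, 5)), pmap, segment=False)
        assert stack.images[0].max() == 0.0

    def test_collision_group_mean(self):
        layout = _layout_from_coords([[0, 0], [1, 1], [0.5, 0.5], [0.5, 0.5]])
        pmap = pixel_assignment(layout, angle=0.0, grid_h=5, grid_w=5)
        X = np.array([[0.0, 0.0, 0.2, 0.6]])
        stack = render_images(X, pmap, epsilon=0.0, segment=False)
        (rc,) = [rc for rc, g in pmap.collision_groups.items() if len(g) == 2]
        assert stack.images[0][rc] == pytest.approx(0.4)

    def test_values_stay_in_unit_interval(self, rng):
        pmap = self._pmap()
        X = rng.uniform(size=(10, 5))
        stack = render_images(X, pmap, epsilon=1 / 255, segment=True)
        assert stack.images.min() >= 0.0 and stack.images.max() <= 1.0

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValidationError):
            render_images(np.zeros((1, 5)), self._pmap(), epsilon=1.0)


class TestSupportMasks:
    def _stack(self, segment, rng):
        layout = _layout_from_coords(rng.normal(size=(20, 2)))
        pmap = pixel_assignment(layout, angle=0.0, grid_h=8, grid_w=8)
        X = rng.uniform(size=(6, 20))
        X[0] = 0.0           # an all-zero-feature sample
        X[1, :10] = 0.0
        return pixel_assignment, render_images(X, pmap, epsilon=1 / 255,
                                               segment=segment), pmap

    def test_segmented_supports_equal_foreground(self, rng):
        _, stack, pmap = self._stack(True, rng)
        for i in range(6):
            np.testing.assert_array_equal(support_mask(stack, i),
                                          pmap.foreground_mask)
        assert distinct_supports(stack) == 1

    def test_unsegmented_supports_differ(self, rng):
        _, stack, pmap = self._stack(False, rng)
        assert distinct_supports(stack) >= 2
        assert support_mask(stack, 0).sum() < pmap.foreground_mask.sum()

    def test_out_of_range_index_rejected(self, rng):
        _, stack, _ = self._stack(True, rng)
        with pytest.raises(DomainError):
            support_mask(stack, 6)


class TestTrainTestHygiene:
    def test_layout_and_stats_ignore_test_rows(self, rng):
        X = rng.normal(size=(30, 25))
        train = np.arange(20)
        layout_a = feature_layout(X[train], method="pca", seed=0)
        norm_a = normalize_values(X, "independent", train_index=train)
        X2 = X.copy()
        X2[20:] += rng.normal(scale=5, size=(10, 25))  # perturb test rows only
        layout_b = feature_layout(X2[train], method="pca", seed=0)
        norm_b = normalize_values(X2, "independent", train_index=train)
        np.testing.assert_array_equal(layout_a.coords2d, layout_b.coords2d)
        np.testing.assert_array_equal(norm_a[train], norm_b[train])


class TestDeterminism:
    def test_bit_identical_stacks_for_fixed_seed(self, rng):
        X = rng.normal(size=(12, 30))

        def build():
            layout = feature_layout(X, method="pca", seed=3)
            angle, _ = min_area_rectangle(layout.coords2d)
            pmap = pixel_assignment(layout, angle, 16, 16)
            return render_images(normalize_values(X, "independent"), pmap)

        a, b = build(), build()
        assert a.images.tobytes() == b.images.tobytes()
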