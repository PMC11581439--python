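import numpy as np
import pytest

from crowdscope.morphology import (
    VolumeStack,
    cell_volume,
    geodesic_distances,
    geodesic_sector_profile,
    height_map,
    nuclear_fraction,
    shape_metrics,
)
from crowdscope.synthetic import synth_cell_phantom


class TestVolume:
    def test_empty_stack_zero(self):
        stack = VolumeStack(np.zeros((5, 8, 8)), (0.1, 0.1, 0.4), threshold=10.0)
        assert cell_volume(stack) == 0.0

    def test_counting_definition(self):
        voxels = np.zeros((4, 4, 4))
        voxels[1, 1, 1] = voxels[2, 2, 2] = voxels[3, 0, 0] = 100.0
        stack = VolumeStack(voxels, (0.1, 0.1, 0.1), threshold=50.0)
        assert cell_volume(stack) == pytest.approx(3 * 0.001)

    def test_digitized_sphere_matches_analytic(self):
        stack, _, truth = synth_cell_phantom(
            "sphere", radius=5.0, voxel_size=(0.1, 0.1, 0.1)
        )
        assert cell_volume(stack) == pytest.approx(truth["analytic_volume"], rel=0.03)
        assert truth["analytic_volume"] == pytest.approx(523.6, abs=0.1)

    def test_volume_additive_over_disjoint_phantoms(self):
        a = np.zeros((6, 10, 10))
        a[1:3, 1:4, 1:4] = 100.0
        b = np.zeros((6, 10, 10))
        b[4:6, 6:9, 6:9] = 100.0
        va = cell_volume(VolumeStack(a, (0.1, 0.1, 0.1), 50.0))
        vb = cell_volume(VolumeStack(b, (0.1, 0.1, 0.1), 50.0))
        vu = cell_volume(VolumeStack(a + b, (0.1, 0.1, 0.1), 50.0))
        assert vu == pytest.approx(va + vb)


class TestHeightMap:
    def test_uniform_slab(self):
        voxels = np.zeros((12, 6, 6))
        voxels[:10] = 100.0
        hm = height_map(VolumeStack(voxels, (0.1, 0.1, 0.4), 50.0))
        np.testing.assert_allclose(hm.height, 4.0)

    def test_empty_column_zero(self):
        voxels = np.zeros((5, 4, 4))
        voxels[:, :2, :] = 100.0
        hm = height_map(VolumeStack(voxels, (0.1, 0.1, 0.4), 50.0))
        assert np.all(hm.height[2:, :] == 0)

    def test_hemisphere_profile(self):
        stack, _, _ = synth_cell_phantom(
            "hemisphere", radius=5.0, voxel_size=(0.1, 0.1, 0.1)
        )
        hm = height_map(stack)
        nz, ny, nx = stack.voxels.shape
        yc, xc = ny * 0.1 / 2, nx * 0.1 / 2
        yy, xx = np.mgrid[0:ny, 0:nx]
        rho = np.hypot((xx + 0.5) * 0.1 - xc, (yy + 0.5) * 0.1 - yc)
        inside = rho < 4.5
        expected = np.sqrt(np.clip(5.0**2 - rho**2, 0, None))
        assert np.max(np.abs(hm.height[inside] - expected[inside])) <= 0.15

    def test_column_sum_identity_with_volume(self):
        stack, _, _ = synth_cell_phantom(
            "spread-cell", radius=4.0, voxel_size=(0.2, 0.2, 0.4)
        )
        hm = height_map(stack)
        dx, dy, _ = stack.voxel_size
        assert float(hm.height.sum()) * dx * dy == pytest.approx(cell_volume(stack))


class TestShapeMetrics:
    def test_disk_circularity_near_one(self):
        yy, xx = np.mgrid[0:128, 0:128]
        disk = (xx - 64) ** 2 + (yy - 64) ** 2 <= 50**2
        m = shape_metrics(disk)
        assert m.circularity == pytest.approx(1.0, abs=0.05)
        assert m.area == float(disk.sum())

    def test_square_circularity_pi_over_four(self):
        mask = np.zeros((128, 128), bool)
        mask[14:114, 14:114] = True
        assert shape_metrics(mask).circularity == pytest.approx(np.pi / 4, abs=0.03)

    def test_elongated_rectangle(self):
        mask = np.zeros((20, 120), bool)
        mask[8:12, 10:110] = True
        # closed form 4*pi*400/208^2 ~ 0.116 for a 100x4 rectangle
        assert shape_metrics(mask).circularity == pytest.approx(0.116, abs=0.03)

    def test_multi_component_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:14] = True
        with pytest.raises(ValueError, match="connected"):
            shape_metrics(mask)


class TestGeodesicSectors:
    def test_constant_field_flat_profile(self, concentric_masks):
        cell, nucleus = concentric_masks
        profile = geodesic_sector_profile(np.full(cell.shape, 0.2), cell, nucleus)
        np.testing.assert_allclose(profile.mean_values, 1.0)
        assert profile.n_pixels.sum() == (cell & ~nucleus).sum()

    def test_default_five_sectors_span_unit_interval(self, concentric_masks):
        cell, nucleus = concentric_masks
        profile = geodesic_sector_profile(np.full(cell.shape, 0.2), cell, nucleus)
        np.testing.assert_allclose(profile.sector_edges,
                                   [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_linear_radial_gradient_reproduced(self, concentric_masks):
        cell, nucleus = concentric_masks
        yy, xx = np.mgrid[0:256, 0:256]
        rho = np.hypot(xx - 128, yy - 128)
        frac = np.clip((rho - 20.0) / 80.0, 0, 1)
        r_map = 0.18 + 0.06 * frac  # 0.18 at the nucleus, 0.24 at the edge
        profile = geodesic_sector_profile(r_map, cell, nucleus, n_sectors=5)
        centers = 0.1 + 0.2 * np.arange(5)
        expected = (0.18 + 0.06 * centers) / (0.18 + 0.06 * 0.1)
        np.testing.assert_allclose(profile.mean_values, expected, rtol=0.02)

    @pytest.mark.parametrize("shape", ["star", "c-shape"])
    def test_constant_field_flat_on_odd_shapes(self, shape):
        yy, xx = np.mgrid[0:200, 0:200]
        cx = cy = 100
        theta = np.arctan2(yy - cy, xx - cx)
        rho = np.hypot(xx - cx, yy - cy)
        if shape == "star":
            cell = rho <= 60 + 25 * np.cos(5 * theta)
            nucleus = rho <= 15
        else:
            cell = (rho <= 80) & ~((rho <= 85) & (np.abs(theta) < 0.6) & (rho > 35))
            nucleus = rho <= 12
        profile = geodesic_sector_profile(np.full(cell.shape, 0.21), cell, nucleus)
        valid = np.isfinite(profile.mean_values)
        np.testing.assert_allclose(profile.mean_values[valid], 1.0)

    def test_normalized_distance_spans_unit_interval(self, concentric_masks):
        cell, nucleus = concentric_masks
        _, _, f = geodesic_distances(cell, nucleus)
        vals = f[np.isfinite(f)]
        assert vals.min() == pytest.approx(0.0, abs=0.05)
        assert vals.max() == pytest.approx(1.0, abs=0.05)

    def test_nucleus_outside_cell_rejected(self):
        cell = np.zeros((10, 10), bool)
        cell[2:8, 2:8] = True
        nucleus = np.zeros((10, 10), bool)
        nucleus[0, 0] = True
        with pytest.raises(ValueError):
            geodesic_distances(cell, nucleus)


class TestNuclearFraction:
    def _masks(self):
        cell = np.zeros((3, 20, 20), bool)
        cell[:, 2:18, 2:18] = True
        nucleus = np.zeros((3, 20, 20), bool)
        nucleus[0, 8:12, 8:12] = True
        nucleus[1, 5:13, 5:13] = True  # largest nucleus area on slice 1
        nucleus[2, 8:12, 8:12] = True
        return cell, nucleus

    def test_all_signal_in_nucleus(self):
        cell, nucleus = self._masks()
        stack = np.where(nucleus, 50.0, 0.0)
        assert nuclear_fraction(stack, cell, nucleus) == 1.0

    def test_uniform_signal_gives_area_ratio(self):
        cell, nucleus = self._masks()
        stack = np.where(cell, 10.0, 0.0)
        expected = nucleus[1].sum() / cell[1].sum()
        assert nuclear_fraction(stack, cell, nucleus) == pytest.approx(expected)

    def test_translocation_fraction_recovered(self):
        cell, nucleus = self._masks()
        cyto = cell & ~nucleus
        # 70% of total signal placed in the nucleus on every slice
        stack = np.zeros(cell.shape)
        for z in range(3):
            stack[z][nucleus[z]] = 0.7 / nucleus[z].sum()
            stack[z][cyto[z]] = 0.3 / cyto[z].sum()
        assert nuclear_fraction(stack, cell, nucleus) == pytest.approx(0.7, abs=0.01)

    def test_zero_cell_intensity_rejected(self):
        cell, nucleus = self._masks()
        with pytest.raises(ValueError, match="zero cell intensity"):
            nuclear_fraction(np.zeros(cell.shape), cell, nucleus)
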