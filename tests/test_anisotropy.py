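import numpy as np
import pytest

from crowdscope.anisotropy import (
    AnisotropyMap,
    GFactorMap,
    anisotropy_timecourse,
    compute_anisotropy_map,
    compute_gfactor_map,
    homo_fret_bleach_test,
    kde_mode,
    modal_anisotropy,
    subtract_background,
)
from crowdscope.polarimetry_io import PolarizedFramePair, RawDualViewFrame, RoiMask
from crowdscope.synthetic import synth_polarized_scene
from crowdscope import polarimetry_io as pio


def make_pair(par, perp):
    return PolarizedFramePair(parallel=par, perpendicular=perp, registered=True)


class TestGFactor:
    def test_ratio_two(self):
        perp = np.full((16, 16), 500.0)
        g = compute_gfactor_map([make_pair(2 * perp, perp)])
        np.testing.assert_allclose(g.g[g.valid], 2.0)

    def test_equal_halves_give_unity(self):
        half = np.full((16, 16), 800.0)
        g = compute_gfactor_map([make_pair(half, half)])
        np.testing.assert_allclose(g.g[g.valid], 1.0)

    def test_vignetted_field_recovered(self, rng):
        h, w = 64, 64
        xx = np.arange(w)[None, :] * np.ones((h, 1))
        g_true = 1.0 + 0.1 * xx / w
        perp = rng.poisson(2000, size=(h, w)).astype(float)
        pairs = [make_pair(perp * g_true, perp) for _ in range(3)]
        g = compute_gfactor_map(pairs)
        assert np.max(np.abs(g.g[g.valid] / g_true[g.valid] - 1)) < 0.01

    def test_empty_stack_fails(self):
        with pytest.raises(ValueError, match="empty"):
            compute_gfactor_map([])

    def test_noise_floor_invalidates(self):
        par = np.full((8, 8), 100.0)
        perp = np.zeros((8, 8))
        g = compute_gfactor_map([make_pair(par, perp)])
        assert not g.valid.any()


class TestSubtractBackground:
    def test_cases(self):
        frame = RawDualViewFrame(np.full((4, 4), 100, dtype=np.uint16))
        bg = RawDualViewFrame(np.full((4, 4), 30, dtype=np.uint16))
        out = subtract_background(frame, bg)
        assert np.all(out.pixels == 70)
        # background equal to the frame zeroes it; zero background is identity
        assert np.all(subtract_background(frame, frame).pixels == 0)
        zero = RawDualViewFrame(np.zeros((4, 4), dtype=np.uint16))
        assert np.all(subtract_background(frame, zero).pixels == 100)

    def test_clip_at_zero(self):
        frame = RawDualViewFrame(np.full((2, 2), 10, dtype=np.uint16))
        bg = RawDualViewFrame(np.full((2, 2), 50, dtype=np.uint16))
        assert np.all(subtract_background(frame, bg).pixels == 0)

    def test_shape_mismatch(self):
        a = RawDualViewFrame(np.zeros((4, 4), dtype=np.uint16))
        b = RawDualViewFrame(np.zeros((4, 6), dtype=np.uint16))
        with pytest.raises(ValueError):
            subtract_background(a, b)


class TestAnisotropyMap:
    def test_equal_channels_zero_r(self):
        par = np.full((8, 8), 30000.0)
        amap = compute_anisotropy_map(
            make_pair(par, par), GFactorMap.uniform((8, 8))
        )
        np.testing.assert_allclose(amap.r[amap.valid], 0.0)

    def test_hand_value(self):
        par = np.full((4, 4), 150.0)
        perp = np.full((4, 4), 100.0)
        amap = compute_anisotropy_map(
            make_pair(par, perp), GFactorMap.uniform((4, 4)),
            threshold_low=0, threshold_high=1e9,
        )
        np.testing.assert_allclose(amap.r, 50.0 / 350.0)

    def test_intensity_window_defaults(self):
        # parallel counts 14,999 / 30,000 / 50,001: only the middle passes
        par = np.array([[14999.0, 30000.0, 50001.0]])
        perp = np.full((1, 3), 10000.0)
        amap = compute_anisotropy_map(make_pair(par, perp), GFactorMap.uniform((1, 3)))
        assert list(amap.valid[0]) == [False, True, False]

    def test_zero_denominator_invalidated(self):
        par = np.zeros((2, 2))
        amap = compute_anisotropy_map(
            make_pair(par, par), GFactorMap.uniform((2, 2)),
            threshold_low=0, threshold_high=1e9,
        )
        assert not amap.valid.any()

    @pytest.mark.parametrize("r_true,g_true", [(0.0, 1.0), (0.22, 1.3), (-0.1, 0.7),
                                               (0.35, 2.5)])
    def test_imposed_field_roundtrip(self, r_true, g_true):
        """I_par = I(1+2r)/3 and I_perp = I(1-r)/(3g) invert to r exactly."""
        shape = (16, 16)
        intensity = np.full(shape, 60000.0)
        r_field = np.full(shape, r_true)
        par = intensity * (1 + 2 * r_field) / 3
        perp = intensity * (1 - r_field) / (3 * g_true)
        g = GFactorMap.uniform(shape, g_true)
        amap = compute_anisotropy_map(make_pair(par, perp), g,
                                      threshold_low=0, threshold_high=1e9)
        np.testing.assert_allclose(amap.r, r_true, atol=1e-10)

    def test_scale_invariance(self, rng):
        par = rng.uniform(20000, 40000, (8, 8))
        perp = rng.uniform(10000, 30000, (8, 8))
        g = GFactorMap.uniform((8, 8), 1.2)
        a1 = compute_anisotropy_map(make_pair(par, perp), g, 0, 1e12)
        a2 = compute_anisotropy_map(make_pair(7.3 * par, 7.3 * perp), g, 0, 1e12)
        np.testing.assert_allclose(a1.r, a2.r, atol=1e-12)


class TestKdeMode:
    def test_constant_sample(self):
        assert kde_mode(np.full(500, 0.25)) == pytest.approx(0.25, abs=1e-4)

    def test_ninety_ten_mixture(self, rng):
        sample = np.concatenate([
            rng.normal(0.20, 0.002, 9000), rng.normal(0.30, 0.002, 1000)
        ])
        assert kde_mode(sample) == pytest.approx(0.20, abs=0.003)
        assert sample.mean() == pytest.approx(0.21, abs=0.001)

    def test_gaussian_sample(self, rng):
        sample = rng.normal(0.22, 0.01, 10_000)
        assert kde_mode(sample) == pytest.approx(0.22, abs=0.002)

    def test_symmetric_mode_matches_mean(self, rng):
        sample = rng.normal(0.18, 0.005, 20_000)
        assert kde_mode(sample) == pytest.approx(sample.mean(), abs=0.002)


class TestModalAnisotropy:
    def _map_with_cells(self, rng):
        r = np.empty((40, 60))
        r[:, :30] = rng.normal(0.20, 0.005, (40, 30))
        r[:, 30:] = rng.normal(0.24, 0.005, (40, 30))
        labels = np.zeros((40, 60), dtype=np.int32)
        labels[:, :30] = 1
        labels[:, 30:] = 2
        amap = AnisotropyMap(r=r, total_intensity=np.full((40, 60), 3e4),
                             valid=np.ones((40, 60), bool))
        return amap, RoiMask(labels=labels)

    def test_per_cell_modes(self, rng):
        amap, roi = self._map_with_cells(rng)
        records = modal_anisotropy(amap, roi)
        assert [r.cell_id for r in records] == [1, 2]
        assert records[0].modal_r == pytest.approx(0.20, abs=0.003)
        assert records[1].modal_r == pytest.approx(0.24, abs=0.003)

    def test_small_cells_skipped(self, rng):
        amap, roi = self._map_with_cells(rng)
        roi.labels[roi.labels == 2] = 0
        roi.labels[0, 30] = 2  # a single-pixel cell
        records = modal_anisotropy(amap, roi)
        assert [r.cell_id for r in records] == [1]


class TestTimecourseAndBleach:
    def _record(self, cell, modal, t=0.0, intensity=1000.0):
        from crowdscope.anisotropy import CellAnisotropyRecord

        return CellAnisotropyRecord(cell_id=cell, modal_r=modal, mean_r=modal,
                                    n_pixels=500, mean_intensity=intensity,
                                    timestamp=t)

    def test_constant_series_zero(self):
        recs = {t: [self._record(1, 0.2, t)] for t in (-60.0, 0.0, 60.0, 120.0)}
        df, summary = anisotropy_timecourse(recs)
        np.testing.assert_allclose(df["delta_r_pct"], 0.0)

    def test_ten_percent_rise(self):
        recs = {0.0: [self._record(1, 0.20)], 60.0: [self._record(1, 0.22)]}
        df, _ = anisotropy_timecourse(recs)
        assert df.loc[df["t"] == 60.0, "delta_r_pct"].iloc[0] == pytest.approx(10.0)

    def test_missing_baseline_excluded(self):
        recs = {0.0: [self._record(1, 0.2)],
                60.0: [self._record(1, 0.21), self._record(2, 0.3)]}
        df, _ = anisotropy_timecourse(recs)
        assert set(df["cell_id"]) == {1}

    def test_bleach_intensity_halved_r_unchanged(self):
        pre = [self._record(1, 0.20, intensity=2000.0)]
        post = [self._record(1, 0.20, intensity=1000.0)]
        out = homo_fret_bleach_test(pre, post)
        assert out[1][0] == pytest.approx(0.0)
        assert out[1][1] == pytest.approx(-50.0)

    def test_bleach_homo_fret_signature(self):
        # bleaching thins fluorophores: intensity falls, r rises
        pre = [self._record(1, 0.20, intensity=3000.0)]
        post = [self._record(1, 0.216, intensity=2100.0)]
        (dr, di) = homo_fret_bleach_test(pre, post)[1]
        assert dr > 0 and di < 0
        assert dr == pytest.approx(8.0, abs=0.01)
        assert di == pytest.approx(-30.0, abs=0.01)


class TestScenePipeline:
    def test_zero_noise_roundtrip_through_full_pipeline(self):
        shape = (64, 64)
        r_field = np.full(shape, 0.2)
        frame, _ = synth_polarized_scene(r_field, np.full(shape, 64000.0))
        pair = pio.split_dual_view(frame)
        pair.registered = True
        amap = compute_anisotropy_map(pair, GFactorMap.uniform(shape))
        assert amap.valid.all()
        np.testing.assert_allclose(amap.r, 0.2, atol=1e-10)

    def test_two_population_mode_follows_dominant_region(self, rng):
        """A dominant perinuclear region sets the modal value even though a
        lamellar region pulls the mean down."""
        shape = (64, 64)
        r_field = np.full(shape, 0.22)
        r_field[:, :20] = 0.19  # minority lamella
        r_field += rng.normal(0, 0.003, shape)
        frame, _ = synth_polarized_scene(r_field, np.full(shape, 64000.0))
        pair = pio.split_dual_view(frame)
        pair.registered = True
        amap = compute_anisotropy_map(pair, GFactorMap.uniform(shape))
        roi = RoiMask(labels=np.ones(shape, dtype=np.int32))
        rec = modal_anisotropy(amap, roi)[0]
        assert rec.modal_r == pytest.approx(0.22, abs=0.004)
        assert rec.mean_r < rec.modal_r
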