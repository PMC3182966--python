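import numpy as np
import pytest

from rppaquant import (ArrayImage, NoiseSpec, detect_dust, inject_dust,
                       locate_grid, net_volume, regional_background,
                       remove_dust, render_array, segment_array, segment_spot)
from rppaquant.background import BackgroundEstimate
from rppaquant.gridding import SpotMeasurement
from rppaquant.pipeline import PipelineConfig, measure_array


def disk_image(level=200, spot=3000, center=(32, 32), radius=10,
               shape=(64, 64)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, level, dtype=float)
    img[np.hypot(yy - center[0], xx - center[1]) <= radius] += spot
    return ArrayImage(img.astype(np.uint16))


class TestRegionalBackground:
    def test_flat_background_estimated_exactly(self):
        image = disk_image(level=237)
        m = segment_spot(image, (32.0, 32.0), 17.0)
        bg = regional_background(image, m)
        assert bg.level == 237.0
        assert not bg.low_confidence

    def test_gradient_recovered_at_spot_centers(self, small_layout,
                                                small_conc, params):
        noise = NoiseSpec(multiplicative_cv=0, read_noise_sd=0,
                          background_level=200, background_gradient=150,
                          spot_jitter_sd=0)
        image, truth = render_array(small_layout, params, small_conc, noise,
                                    seed=3)
        grid = locate_grid(image, small_layout)
        ms = segment_array(image, small_layout, grid)
        occupancy = np.zeros(image.shape, bool)
        for m in ms:
            occupancy |= m.full_mask(image.shape)
        for m in ms:
            bg = regional_background(image, m, occupancy=occupancy)
            cy, cx = int(round(m.center[0])), int(round(m.center[1]))
            true_level = truth.background[cy, cx]
            assert bg.level == pytest.approx(true_level, rel=0.02)

    def test_crowded_annulus_grows_or_flags_without_raising(self):
        image = disk_image()
        m = segment_spot(image, (32.0, 32.0), 17.0)
        occupancy = np.ones(image.shape, dtype=bool)
        occupancy[:2, :] = False  # only a remote sliver is eligible
        bg = regional_background(image, m, occupancy=occupancy)
        assert isinstance(bg, BackgroundEstimate)


class TestNetVolume:
    def test_arithmetic(self):
        m = SpotMeasurement(address=(0, 0, 0), center=(0, 0), bbox=(0, 0),
                            mask=np.ones((10, 10), bool), area=100,
                            raw_volume=10000.0)
        bg = BackgroundEstimate(level=20.0, inner_radius=1, outer_radius=2,
                                n_pixels=50)
        assert net_volume(m, bg) == 8000.0

    def test_floored_at_zero_with_flag(self):
        m = SpotMeasurement(address=(0, 0, 0), center=(0, 0), bbox=(0, 0),
                            mask=np.ones((5, 5), bool), area=25,
                            raw_volume=100.0)
        bg = BackgroundEstimate(level=10.0, inner_radius=1, outer_radius=2,
                                n_pixels=50)
        assert net_volume(m, bg) == 0.0
        assert "negative_net" in m.flags

    def test_constant_offset_leaves_net_volumes_unchanged(
            self, small_layout, small_conc, params):
        """Adding a constant to every pixel must cancel exactly."""
        image, _ = render_array(small_layout, params, small_conc,
                                NoiseSpec(), seed=11)
        shifted = ArrayImage(image.pixels + np.uint16(500), 16,
                             image.pixel_size)
        cfg = PipelineConfig(dust_removal=False)
        *_, obs0 = measure_array(image, small_layout, cfg)
        *_, obs1 = measure_array(shifted, small_layout, cfg)
        for a, b in zip(obs0, obs1):
            assert b.y == pytest.approx(a.y, abs=1e-6)


class TestDetectDust:
    def test_clean_spot_returns_none(self, rendered_clean, small_layout):
        image, _ = rendered_clean
        grid = locate_grid(image, small_layout)
        for m in segment_array(image, small_layout, grid):
            assert detect_dust(image, m) is None

    def test_injected_speck_detected_and_removed(self, rendered_clean,
                                                 small_layout):
        image, truth = rendered_clean
        dusty, t2 = inject_dust(image, truth, 5, seed=9, on_spot_fraction=1.0,
                                volume_fraction_range=(0.25, 0.4))
        grid = locate_grid(dusty, small_layout)
        ms = {m.address: m for m in segment_array(dusty, small_layout, grid)}
        for speck in t2.dust:
            m = ms[speck.on_spot]
            rec = detect_dust(dusty, m)
            assert rec is not None
            if rec.action != "removed":
                continue
            fixed = remove_dust(dusty, m, rec)
            assert "dust_corrected" in fixed.flags
            truth_vol = t2.spots[speck.on_spot].net_volume
            contaminated_err = abs(m.raw_volume - truth_vol)
            corrected_err = abs(fixed.raw_volume - truth_vol)
            # removal never worsens the volume, and lands near truth
            assert corrected_err <= contaminated_err
            bg_pp = 100.0  # flat clean background level per pixel
            net = fixed.raw_volume - bg_pp * fixed.area
            assert net == pytest.approx(truth_vol, rel=0.05)

    def test_large_speck_excludes_spot(self):
        image = disk_image(level=100, spot=2000)
        m = segment_spot(image, (32.0, 32.0), 17.0)
        vals = image.pixels.astype(np.int64)
        yy, xx = np.mgrid[0:64, 0:64]
        blob = np.hypot(yy - 28, xx - 32) <= 7  # ~40% of the spot area
        vals[blob & m.full_mask(image.shape)] += 30000
        dusty = ArrayImage(np.clip(vals, 0, 65535).astype(np.uint16))
        m2 = segment_spot(dusty, (32.0, 32.0), 17.0)
        rec = detect_dust(dusty, m2)
        assert rec is not None
        assert rec.action == "spot_excluded"
        with pytest.raises(ValueError):
            remove_dust(dusty, m2, rec)

    def test_missing_spot_rejected(self):
        m = SpotMeasurement(address=(0, 0, 0), center=(0, 0), bbox=(0, 0),
                            mask=np.ones((5, 5), bool), area=25,
                            raw_volume=0.0, flags={"missing"})
        with pytest.raises(ValueError):
            detect_dust(disk_image(), m)
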