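import numpy as np
import pytest

from rppaquant import (ArrayImage, GridNotFoundError, NoiseSpec, dice,
                       locate_grid, make_dilution_layout, render_array,
                       segment_array, segment_spot)


class TestLocateGrid:
    def test_zero_shift_recovered_within_a_pixel(self, rendered, small_layout):
        image, _ = rendered
        grid = locate_grid(image, small_layout)
        assert abs(grid.shift[0]) <= 1.0
        assert abs(grid.shift[1]) <= 1.0

    def test_known_global_shift_recovered(self, small_layout, small_conc,
                                          params):
        noise = NoiseSpec(spot_jitter_sd=0.0, global_shift=(37.0, -22.0))
        image, _ = render_array(small_layout, params, small_conc, noise,
                                seed=2)
        grid = locate_grid(image, small_layout)
        assert grid.shift[0] == pytest.approx(3.7, abs=1.0)
        assert grid.shift[1] == pytest.approx(-2.2, abs=1.0)

    def test_pure_noise_raises_grid_not_found(self, small_layout, rng):
        pixels = rng.integers(100, 160, size=(220, 580)).astype(np.uint16)
        with pytest.raises(GridNotFoundError):
            locate_grid(ArrayImage(pixels), small_layout)


class TestSegmentSpot:
    def test_noiseless_spot_high_dice(self, rendered_clean, small_layout):
        image, truth = rendered_clean
        grid = locate_grid(image, small_layout)
        ms = segment_array(image, small_layout, grid)
        for i, m in enumerate(ms):
            d = dice(truth.labels == i + 1, m.full_mask(image.shape))
            assert d >= 0.95

    def test_displaced_spot_still_captured(self, params):
        """A single spot 30% of the pitch off its nominal center."""
        layout = make_dilution_layout(["a"], n_steps=1, n_replicates=1)
        shift = 0.3 * layout.pitch  # µm
        noise = NoiseSpec(multiplicative_cv=0, read_noise_sd=2,
                          background_level=120, background_gradient=0,
                          spot_jitter_sd=0, global_shift=(shift, 0.0))
        image, truth = render_array(layout, params, {"a": 0.5}, noise, seed=1)
        center = layout.nominal_center((0, 0, 0))
        m = segment_spot(image, center, 0.5 * layout.pitch_px,
                         address=(0, 0, 0))
        assert "missing" not in m.flags
        true_c = truth.spots[(0, 0, 0)].center
        assert abs(m.center[0] - true_c[0]) <= 2.0
        assert abs(m.center[1] - true_c[1]) <= 2.0

    def test_background_only_window_flagged_missing(self, rng):
        pixels = (150 + rng.normal(0, 5, (64, 64))).astype(np.uint16)
        m = segment_spot(ArrayImage(pixels), (32.0, 32.0), 17.0)
        assert "missing" in m.flags
        assert m.area > 0  # fallback disk retained for bookkeeping

    def test_window_outside_image_rejected(self, rng):
        pixels = np.zeros((40, 40), dtype=np.uint16)
        with pytest.raises(ValueError, match="window"):
            segment_spot(ArrayImage(pixels), (5.0, 5.0), 17.0)


class TestSegmentArray:
    def test_one_measurement_per_spot_in_order(self, rendered, small_layout):
        image, _ = rendered
        grid = locate_grid(image, small_layout)
        ms = segment_array(image, small_layout, grid)
        assert [m.address for m in ms] == [s.address for s in
                                           small_layout.spots]

    def test_absent_spots_flagged_missing(self, small_layout, small_conc,
                                          params):
        conc = dict(small_conc)
        conc.pop("s2")  # sample s2 not printed
        image, _ = render_array(small_layout, params, conc, NoiseSpec(),
                                seed=6)
        grid = locate_grid(image, small_layout)
        ms = segment_array(image, small_layout, grid)
        for ann, m in zip(small_layout.spots, ms):
            if ann.sample_id == "s2":
                assert "missing" in m.flags
            else:
                assert "missing" not in m.flags

    def test_determinism(self, rendered, small_layout):
        image, _ = rendered
        grid = locate_grid(image, small_layout)
        a = segment_array(image, small_layout, grid)
        b = segment_array(image, small_layout, grid)
        for ma, mb in zip(a, b):
            assert ma.center == mb.center
            np.testing.assert_array_equal(ma.mask, mb.mask)

    def test_integer_shift_equivariance(self, small_layout, small_conc,
                                        params):
        """Rolling the image by whole pixels rolls every recovered center
        and mask by exactly the same amount."""
        noise = NoiseSpec(spot_jitter_sd=0.0)
        image, _ = render_array(small_layout, params, small_conc, noise,
                                seed=8)
        dy, dx = 9, -7  # < 40% of the 35 px pitch
        rolled = ArrayImage(np.roll(image.pixels, (dy, dx), axis=(0, 1)),
                            16, image.pixel_size)
        m0 = segment_array(image, small_layout,
                           locate_grid(image, small_layout))
        m1 = segment_array(rolled, small_layout,
                           locate_grid(rolled, small_layout))
        shape = image.shape
        for a, b in zip(m0, m1):
            if "missing" in a.flags or "missing" in b.flags:
                continue
            assert b.center[0] - a.center[0] == pytest.approx(dy, abs=0.51)
            assert b.center[1] - a.center[1] == pytest.approx(dx, abs=0.51)
            fa = np.roll(a.full_mask(shape), (dy, dx), axis=(0, 1))
            assert dice(fa, b.full_mask(shape)) > 0.97

    def test_raw_volume_additivity(self, rendered, small_layout):
        image, _ = rendered
        grid = locate_grid(image, small_layout)
        m = segment_array(image, small_layout, grid)[0]
        bumped = image.pixels.astype(np.int64).copy()
        y0, x0 = m.bbox
        ys, xs = np.nonzero(m.mask)
        bumped[ys[:5] + y0, xs[:5] + x0] += 100  # D = 500 inside the mask
        new_raw = float(bumped[m.full_mask(image.shape)].sum())
        assert new_raw - m.raw_volume == pytest.approx(500.0)
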