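"""Image quantification estimators: stereology, counting frames, coherency,
wall thickness, radiodensity."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from captrans.capsule_quant import (
    capsule_thickness,
    coherency,
    point_grid_fraction,
    radiodensity,
    relative_volume,
    vessel_density,
)


class TestPointGridFraction:
    def test_all_positive(self):
        mask = np.ones((200, 200), bool)
        for seed in (0, 1, 2):
            assert point_grid_fraction(mask, 40, 4, seed).fraction == 1.0

    def test_all_negative(self):
        mask = np.zeros((200, 200), bool)
        assert point_grid_fraction(mask, 40, 4, seed=0).fraction == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        mask = rng.random((128, 128)) > 0.5
        a = point_grid_fraction(mask, 50, 4, seed=11)
        b = point_grid_fraction(mask, 50, 4, seed=11)
        assert (a.n_positive_hits, a.n_total_points) == (b.n_positive_hits, b.n_total_points)

    def test_spacing_below_pixel_rejected(self):
        with pytest.raises(ValueError):
            point_grid_fraction(np.ones((10, 10), bool), 1.0, 4.0, 0)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            point_grid_fraction(np.ones((4, 4), bool), 1000.0, 1.0, 0)


class TestRelativeVolume:
    def test_published_formula(self):
        assert relative_volume(0.2, 0.1) == pytest.approx(2.0)

    def test_alternative_reading(self):
        assert relative_volume(0.2, 0.1, mode="prose") == pytest.approx(0.02)

    def test_zero_fraction(self):
        assert relative_volume(0.0, 0.1) == 0.0
        assert relative_volume(0.0, 0.1, mode="prose") == 0.0

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            relative_volume(0.2, 0.0)


class TestVesselDensity:
    def test_counts_per_total_frame_area(self):
        # 5 vessels over 10 frames of 2000 μm² -> 2.5e-4 per μm²
        frames = np.array([[100.0 * k, 0.0, 100.0 * k + 50.0, 40.0] for k in range(10)])
        marks = np.array([[100.0 * k + 25.0, 20.0] for k in range(5)])
        assert vessel_density(marks, frames) == pytest.approx(2.5e-4)

    def test_no_vessels(self):
        frames = np.array([[0.0, 0.0, 50.0, 40.0]])
        assert vessel_density(np.empty((0, 2)), frames) == 0.0

    def test_forbidden_line_rule(self):
        frame = np.array([[10.0, 10.0, 60.0, 50.0]])
        on_left = np.array([[10.0, 30.0]])
        on_bottom = np.array([[35.0, 10.0]])
        on_right = np.array([[60.0, 30.0]])
        on_top = np.array([[35.0, 50.0]])
        assert vessel_density(on_left, frame) == 0.0
        assert vessel_density(on_bottom, frame) == 0.0
        assert vessel_density(on_right, frame) > 0.0
        assert vessel_density(on_top, frame) > 0.0

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(5)
        frames = np.array([[100.0 * k, 0.0, 100.0 * k + 50.0, 40.0] for k in range(8)])
        marks = rng.uniform(0, 800, size=(30, 2)) * [1, 0.05]
        d1 = vessel_density(marks, frames)
        d2 = vessel_density(marks, frames[::-1])
        assert d1 == pytest.approx(d2)

    def test_verbatim_product_mode(self):
        frame = np.array([[0.0, 0.0, 40.0, 50.0]])
        marks = np.array([[20.0, 25.0]])
        val = vessel_density(marks, frame, mode="verbatim", grid_points_per_frame=4)
        assert val == pytest.approx(1 * 4 * 2000.0)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            vessel_density(np.empty((0, 2)), np.empty((0, 4)))


class TestCoherency:
    def test_vertical_stripes_highly_coherent(self):
        x = np.arange(128)
        img = np.tile(np.sin(2 * np.pi * x / 8.0), (128, 1))
        assert coherency(img).coherency >= 0.95

    def test_uniform_image_zero_by_convention(self):
        assert coherency(np.full((64, 64), 3.7)).coherency == 0.0

    def test_rotation_invariance_90_degrees(self):
        rng = np.random.default_rng(0)
        img = rng.random((96, 96))
        img += np.tile(np.sin(np.arange(96) / 3.0), (96, 1))
        c0 = coherency(img).coherency
        c90 = coherency(np.rot90(img)).coherency
        assert abs(c0 - c90) <= 0.02

    def test_small_roi_rejected(self):
        with pytest.raises(ValueError):
            coherency(np.zeros((64, 64)), roi=(0, 0, 4, 4))


class TestCapsuleThickness:
    def test_constant_band(self):
        mask = np.zeros((256, 512), bool)
        mask[78:178, :] = True  # 100 px
        res = capsule_thickness(mask, pixel_size=2.0)
        assert res.mean_um == pytest.approx(200.0, abs=2.0)  # ±1 px

    def test_two_half_bands_bimodal(self):
        mask = np.zeros((256, 512), bool)
        mask[103:153, :256] = True   # 50 px
        mask[78:178, 256:] = True    # 100 px
        res = capsule_thickness(mask, pixel_size=1.0)
        assert res.mean_um == pytest.approx(75.0, abs=1.0)
        assert res.per_location_um.min() < 60 and res.per_location_um.max() > 90

    def test_rotation_invariance(self):
        band = np.zeros((300, 600), bool)
        band[130:170, :] = True  # 40 px
        rot = rotate(band.astype(float), 30, reshape=True, order=0) > 0.5
        t0 = capsule_thickness(band, 1.0).mean_um
        t30 = capsule_thickness(rot, 1.0).mean_um
        assert abs(t0 - t30) <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            capsule_thickness(np.zeros((32, 32), bool), 1.0)


class TestRadiodensity:
    def test_background_subtraction(self):
        img = np.full((64, 64), 100.0)
        img[:32, :32] = 500.0
        val = radiodensity(img, [[0, 0, 16, 16]], [[40, 40, 56, 56]])
        assert val == pytest.approx(400.0)

    def test_identical_regions(self):
        img = np.arange(64.0).reshape(8, 8)
        with pytest.warns(UserWarning, match="overlap"):
            assert radiodensity(img, [[0, 0, 8, 8]], [[0, 0, 8, 8]]) == pytest.approx(0.0)

    def test_constant_image(self):
        img = np.full((32, 32), 7.0)
        assert radiodensity(img, [[0, 0, 8, 8]], [[16, 16, 30, 30]]) == 0.0

    def test_rectangle_outside_image_rejected(self):
        with pytest.raises(ValueError):
            radiodensity(np.zeros((16, 16)), [[0, 0, 32, 32]], [[0, 0, 4, 4]])
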