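import numpy as np
import pytest

from holoshear.metrics import (
    Region,
    correct_orientation,
    lowpass_2x2,
    measure_region,
    reconnect_chains,
    segment,
    wrap_theta,
)


def region_from_mask(mask):
    return Region(pixels=np.column_stack(np.nonzero(mask)))


class TestLowpass:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.7)
        assert np.allclose(lowpass_2x2(img), 0.7)

    def test_hot_pixel_spreads_to_four_quarters(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        out = lowpass_2x2(img)
        assert np.isclose(out.sum(), 1.0)
        assert np.count_nonzero(out) == 4
        assert np.allclose(out[out > 0], 0.25)

    def test_checkerboard_collapses_to_mean(self):
        img = np.indices((16, 16)).sum(axis=0) % 2
        out = lowpass_2x2(img.astype(float))
        assert np.allclose(out[1:-1, 1:-1], 0.5)


class TestSegmentation:
    def test_minimum_size_rule(self):
        """A 4 px blob is noise; a 5 px blob is a particle."""
        img = np.ones((32, 32))
        img[2:4, 2:4] = 0.0  # 4 px
        img[10:11, 10:15] = 0.0  # 5 px
        regions = segment(img, intensity_threshold=0.5)
        assert len(regions) == 1
        assert len(regions[0]) == 5

    def test_blank_image_yields_empty_list(self):
        assert segment(np.ones((32, 32)), intensity_threshold=0.5) == []

    def test_diagonal_pixels_are_8_connected(self):
        img = np.ones((16, 16))
        for k in range(6):
            img[k + 2, k + 2] = 0.0
        assert len(segment(img, intensity_threshold=0.5)) == 1

    def test_annulus_filled_area_counts_hole(self):
        """Interior holes are filled before the area used for D."""
        yy, xx = np.mgrid[0:41, 0:41]
        rr = np.hypot(yy - 20, xx - 20)
        img = np.ones((41, 41))
        img[(rr >= 8) & (rr <= 12)] = 0.0
        ring_px = int(((rr >= 8) & (rr <= 12)).sum())
        hole_px = int((rr < 8).sum())
        (region,) = segment(img, intensity_threshold=0.5)
        rec = measure_region(region, pitch_um=1.0)
        assert rec.area_px == ring_px
        assert rec.filled_area_um2 == pytest.approx(ring_px + hole_px)


class TestChainReconnection:
    def test_zero_gap_is_identity(self):
        regions = [
            region_from_mask(np.pad(np.ones((3, 3), bool), ((0, 0), (k, 10 - k))))
            for k in (0, 6)
        ]
        assert len(reconnect_chains(regions, max_gap_px=0.0)) == 2

    def test_collinear_cells_merge_into_one_chain(self):
        """Five cells with 1 px gaps merge transitively into one region."""
        img = np.ones((20, 60))
        for k in range(5):
            img[8:12, 2 + k * 11 : 12 + k * 11] = 0.0  # 10 px cells, 1 px gaps
        regions = segment(img, intensity_threshold=0.5)
        assert len(regions) == 5
        merged = reconnect_chains(regions, max_gap_px=1.5)
        assert len(merged) == 1
        assert merged[0].chain_flag

    def test_distant_cells_stay_separate(self):
        img = np.ones((20, 120))
        img[8:12, 2:12] = 0.0
        img[8:12, 62:72] = 0.0  # 50 px apart
        merged = reconnect_chains(segment(img, intensity_threshold=0.5), max_gap_px=30 / 4.59)
        assert len(merged) == 2

    def test_merge_order_independent(self):
        img = np.ones((20, 60))
        for k in range(4):
            img[8:12, 2 + k * 12 : 12 + k * 12] = 0.0
        regions = segment(img, intensity_threshold=0.5)
        a = reconnect_chains(regions, max_gap_px=2.5)
        b = reconnect_chains(regions[::-1], max_gap_px=2.5)
        assert len(a) == len(b) == 1
        assert np.array_equal(
            np.sort(a[0].pixels.view("i8,i8"), axis=0), np.sort(b[0].pixels.view("i8,i8"), axis=0)
        )


def digitized_ellipse(a_px, b_px, angle_deg, shape=(160, 160)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = shape[0] / 2, shape[1] / 2
    t = np.radians(angle_deg)
    u = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
    v = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


class TestMorphometry:
    def test_equivalent_diameter_formula(self):
        """A filled area of 78.54 um^2 maps to D = 10 um; 105.3 um^2 (the
        5-pixel minimum at 4.59 um pitch) maps to 11.6 um."""
        yy, xx = np.mgrid[0:21, 0:21]
        disk = np.hypot(yy - 10, xx - 10) <= 8
        rec = measure_region(region_from_mask(disk), pitch_um=1.0)
        area = rec.filled_area_um2
        assert rec.equiv_diam_um == pytest.approx(np.sqrt(4 * area / np.pi))
        assert np.sqrt(4 * 78.54 / np.pi) == pytest.approx(10.0, abs=0.001)
        assert np.sqrt(4 * 5 * 4.59**2 / np.pi) == pytest.approx(11.6, abs=0.05)

    def test_digitized_ellipse_orientation_and_aspect(self):
        """60 x 10 px ellipse at 30 deg: orientation within 1 deg, aspect 6 +- 0.5."""
        mask = digitized_ellipse(30, 5, 30.0)
        rec = measure_region(region_from_mask(mask), pitch_um=1.0)
        assert rec.theta_deg == pytest.approx(30.0, abs=1.0)
        assert rec.aspect_ratio == pytest.approx(6.0, abs=0.5)

    @pytest.mark.parametrize("phi", [-72.0, -35.0, 0.0, 18.0, 45.0, 63.0, 89.0])
    def test_rotation_equivariance(self, phi):
        """Rotating the mask rotates the measured angle, within 1 deg."""
        mask = digitized_ellipse(32, 6, phi)
        rec = measure_region(region_from_mask(mask), pitch_um=1.0)
        err = (rec.theta_deg - phi + 90.0) % 180.0 - 90.0
        assert abs(err) <= 1.0

    @pytest.mark.parametrize("phi", [0.0, 30.0, 75.0])
    @pytest.mark.parametrize("scale", [1.0, 1.8])
    def test_aspect_and_diameter_invariants(self, phi, scale):
        """r is rotation/scale invariant within 10%; D within 2% under rotation."""
        base = measure_region(
            region_from_mask(digitized_ellipse(30, 6, 0.0)), pitch_um=1.0
        )
        other = measure_region(
            region_from_mask(digitized_ellipse(30 * scale, 6 * scale, phi)), pitch_um=1.0 / scale
        )
        assert other.aspect_ratio == pytest.approx(base.aspect_ratio, rel=0.10)
        assert other.equiv_diam_um == pytest.approx(base.equiv_diam_um, rel=0.02)

    def test_degenerate_single_row_region_flagged(self):
        mask = np.zeros((5, 20), bool)
        mask[2, 2:18] = True
        rec = measure_region(region_from_mask(mask), pitch_um=1.0)
        assert rec.minor_um == pytest.approx(1.0)
        assert rec.curvature_flag

    def test_region_below_minimum_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2:4] = True
        with pytest.raises(ValueError):
            measure_region(region_from_mask(mask), pitch_um=1.0)


class TestCurvatureFlag:
    def test_straight_rod_not_flagged(self):
        mask = np.zeros((10, 60), bool)
        mask[3:7, :] = True
        assert not measure_region(region_from_mask(mask), 1.0).curvature_flag

    def test_quarter_arc_flagged(self):
        """Arc length pi*r/2 exceeds the chord r*sqrt(2) by 11%."""
        yy, xx = np.mgrid[0:46, 0:46]
        rr = np.hypot(yy, xx)
        mask = (rr >= 38) & (rr <= 42)
        assert measure_region(region_from_mask(mask), 1.0).curvature_flag

    def test_l_shape_flagged(self):
        mask = np.zeros((40, 40), bool)
        mask[0:6, 0:40] = True
        mask[0:40, 0:6] = True
        assert measure_region(region_from_mask(mask), 1.0).curvature_flag


class TestPitchCorrection:
    @pytest.mark.parametrize(
        "raw,pitch,expected", [(26.0, 6.0, 20.0), (-88.0, 6.0, 86.0), (45.0, 0.0, 45.0)]
    )
    def test_examples(self, raw, pitch, expected):
        assert correct_orientation(raw, pitch) == pytest.approx(expected)

    def test_result_always_in_half_open_interval(self):
        rng = np.random.default_rng(0)
        for raw, pitch in zip(rng.uniform(-90, 90, 200), rng.uniform(-44, 44, 200)):
            out = correct_orientation(raw, pitch)
            assert -90.0 < out <= 90.0

    def test_excessive_pitch_rejected(self):
        with pytest.raises(ValueError):
            correct_orientation(0.0, 50.0)

    def test_wrap_is_periodic(self):
        for t in (-250.0, -90.0, 0.0, 90.0, 123.0):
            assert wrap_theta(t) == pytest.approx(wrap_theta(t + 180.0))
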