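"""Stimulus generators: printed constraints, determinism, ROI structure."""

import numpy as np
import pytest

import retinaglare as rg
from retinaglare.targets import GRAY, WHITE, BLACK


class TestContrastAssimilation:
    @pytest.mark.parametrize(
        "variant,f_white,f_black",
        [("A", 0.57, 0.29), ("B", 0.57, 0.29), ("C", 0.29, 0.57), ("D", 0.29, 0.57)],
    )
    def test_area_fractions(self, variant, f_white, f_black):
        b = rg.make_contrast_assimilation(variant, 512)
        f = b.digit_fractions()
        assert f[WHITE] == pytest.approx(f_white, abs=0.01)
        assert f[BLACK] == pytest.approx(f_black, abs=0.01)
        assert f[GRAY] == pytest.approx(0.14, abs=0.01)

    def test_outer_band_colors(self):
        for v, color in (("A", WHITE), ("B", WHITE), ("C", BLACK), ("D", BLACK)):
            m = rg.make_contrast_assimilation(v, 512).map.digits
            assert (m[0, :] == color).all() and (m[:, 0] == color).all()

    def test_surround_size_ordering(self):
        sizes = {
            v: rg.make_contrast_assimilation(v, 512).metadata["surround_side_px"]
            for v in "ABCD"
        }
        assert sizes["A"] > sizes["B"]
        assert sizes["C"] > sizes["D"]

    def test_gray_segments_identical_digits_and_locations(self):
        bundles = {v: rg.make_contrast_assimilation(v, 512) for v in "ABCD"}
        gray_masks = {v: b.map.digits == GRAY for v, b in bundles.items()}
        for b in bundles.values():
            for name, mask in b.rois.items():
                if name.startswith("gray"):
                    assert set(np.unique(b.map.digits[mask])) == {GRAY}
        # ROI masks sit at the same coordinates in every variant
        ref = bundles["A"].rois
        for v in "BCD":
            for name in ref:
                if name.startswith("gray"):
                    np.testing.assert_array_equal(bundles[v].rois[name], ref[name])

    def test_roi_pairs_disjoint(self):
        b = rg.make_contrast_assimilation("A", 512)
        for darker, lighter in b.appearance_order:
            assert not (b.rois[darker] & b.rois[lighter]).any()

    def test_equal_scene_luminance_of_roi_pairs(self):
        b = rg.make_contrast_assimilation("C", 512)
        scene = b.scene_luminance().values
        for darker, lighter in b.appearance_order:
            assert scene[b.rois[darker]].mean() == scene[b.rois[lighter]].mean()

    def test_deterministic(self):
        a1 = rg.make_contrast_assimilation("B", 512)
        a2 = rg.make_contrast_assimilation("B", 512)
        np.testing.assert_array_equal(a1.map.digits, a2.map.digits)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            rg.make_contrast_assimilation("A", 128)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            rg.make_contrast_assimilation("E")


@pytest.fixture(scope="module")
def bundle():
    return rg.make_todorovic()


class TestTodorovic:
    def test_cross_arm_bounding_box(self, bundle):
        cy, cx = 1536, 512
        cross = bundle.rois["cross_control_left"]
        arm = cross[cy - 12 : cy + 13, :]
        assert arm.shape[0] == 25
        cols = np.flatnonzero(arm.any(axis=0))
        assert cols[-1] - cols[0] + 1 == 380
        rows = np.flatnonzero(cross.any(axis=1))
        assert rows[-1] - rows[0] + 1 == 380

    def test_eight_identical_gray_segments(self, bundle):
        m = bundle.map.digits
        gray_rois = [n for n in bundle.rois]
        assert len(gray_rois) == 8
        for name in gray_rois:
            assert set(np.unique(m[bundle.rois[name]])) == {GRAY}

    def test_control_scans_traverse_same_level_sequence(self, bundle):
        """Both recorded scan rows cross the same set-digit levels
        (background, gray, background, ...) in the control half."""
        m = bundle.map.digits
        half = m.shape[1] // 2

        def level_sequence(row):
            vals = m[row, :half].astype(int)
            return [int(v) for v, prev in zip(vals, np.r_[-1, vals[:-1]]) if v != prev]

        seq_circles = level_sequence(bundle.metadata["scan_rows"]["circles"])
        seq_crosses = level_sequence(bundle.metadata["scan_rows"]["crosses"])
        assert seq_circles == seq_crosses

    def test_max_min_edge_distance(self, bundle):
        # 46 arcmin at 0.293 arcmin/pixel = 157 px from circle center to
        # the shared Black|White edge
        assert bundle.metadata["max_min_edge_offset_px"] == 157
        assert bundle.geometry.arcmin_per_pixel == pytest.approx(0.29296875)

    def test_bad_aspect_rejected(self):
        with pytest.raises(ValueError):
            rg.make_todorovic((2048, 2048))

    def test_too_small_for_cross_rejected(self):
        with pytest.raises(ValueError):
            rg.make_todorovic((16, 32))


class TestCenteredSquare:
    def test_two_level_map_and_area(self):
        b = rg.make_centered_square(2049, 601)
        m = b.map.digits
        assert set(np.unique(m)) == {BLACK, WHITE}
        assert (m == WHITE).sum() / m.size == pytest.approx((601 / 2049) ** 2, rel=1e-9)

    def test_boundary_ring_is_one_pixel_perimeter(self):
        b = rg.make_centered_square(257, 75)
        ring = b.rois["boundary_ring"]
        sq = b.rois["square"]
        assert ring.sum() == 4 * 75 - 4
        assert (ring & sq).sum() == ring.sum()  # ring lies on the square side
        # every ring pixel touches the background 4-neighborhood
        bg = ~sq
        shifted = bg[:-2, 1:-1] | bg[2:, 1:-1] | bg[1:-1, :-2] | bg[1:-1, 2:]
        assert shifted[ring[1:-1, 1:-1]].all()

    def test_even_sizes_rejected(self):
        with pytest.raises(ValueError):
            rg.make_centered_square(2048, 601)
        with pytest.raises(ValueError):
            rg.make_centered_square(2049, 600)


class TestMondrian:
    def test_deterministic_under_seed(self):
        m1 = rg.make_mondrian(5, size=512)
        m2 = rg.make_mondrian(5, size=512)
        np.testing.assert_array_equal(m1.map.digits, m2.map.digits)

    def test_different_seed_different_map(self):
        m1 = rg.make_mondrian(5, size=512)
        m2 = rg.make_mondrian(6, size=512)
        assert not np.array_equal(m1.map.digits, m2.map.digits)

    def test_circle_centers_equal_luminance(self):
        b = rg.make_mondrian(3, size=512)
        scene = b.scene_luminance().values
        ct, cb = b.metadata["circle_centers"]["top"], b.metadata["circle_centers"]["bottom"]
        assert scene[tuple(ct)] == pytest.approx(scene[tuple(cb)], rel=1e-9)

    def test_circle_centers_at_eighty_percent_of_range(self):
        b = rg.make_mondrian(3, size=512)
        scene = b.scene_luminance().values
        ct = b.metadata["circle_centers"]["top"]
        pct = rg.percent_of_range(scene[tuple(ct)], scene.max(), rg.LogRange(2.3))
        assert pct == pytest.approx(80.0, abs=1.0)

    def test_minimum_patch_count_enforced(self):
        with pytest.raises(ValueError):
            rg.make_mondrian(0, n_patches=5)

    def test_gradient_brighter_at_bottom(self):
        b = rg.make_mondrian(2, size=512)
        d = b.map.digits.astype(float)
        assert d[-64:, :].mean() > d[:64, :].mean()


class TestInvert:
    def test_involution_and_endpoints(self):
        b = rg.make_contrast_assimilation("A", 512)
        neg = rg.invert(b)
        assert (neg.map.digits[b.map.digits == 255] == 0).all()
        back = rg.invert(neg)
        np.testing.assert_array_equal(back.map.digits, b.map.digits)

    def test_linear_calibration_preserves_roi_equality(self):
        b = rg.make_mondrian(4, size=512)
        neg = rg.invert(b, appearance_order=[("circle_top", "circle_bottom")])
        flags = neg.metadata["equal_luminance_after_inversion"]
        assert all(flags.values())
        scene = neg.scene_luminance().values
        ct, cb = neg.metadata["circle_centers"]["top"], neg.metadata["circle_centers"]["bottom"]
        assert scene[tuple(ct)] == pytest.approx(scene[tuple(cb)], rel=1e-12)

    def test_nonlinear_calibration_flags_inequality(self):
        b = rg.make_contrast_assimilation("A", 512)
        neg = rg.invert(b)
        # the three-point display calibration is nonlinear in digits, so
        # negated gray pairs no longer calibrate to equal luminance pairs
        # of their negated surround digits; the flag machinery runs on the
        # declared pairs of the source ordering
        assert "equal_luminance_after_inversion" in neg.metadata
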