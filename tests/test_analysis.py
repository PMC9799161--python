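"""ROI statistics, ranges, histograms, scans, paradox reports."""

import numpy as np
import pytest

import retinaglare as rg
from retinaglare.gsf import AngularGeometry
from retinaglare.targets import TargetBundle, DigitMap
from retinaglare.calibration import DisplayCalibration


class TestRoiStats:
    def test_hand_computed_toy_roi(self):
        img = np.array(
            [[1.0, 0.5, 0.25, 0.125, 1.0],
             [0.5, 0.1, 0.2, 0.4, 0.5],
             [1.0, 0.8, 0.01, 0.2, 1.0],
             [0.5, 0.4, 0.2, 0.1, 0.5],
             [1.0, 0.5, 0.25, 0.125, 1.0]]
        )
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        st = rg.roi_stats(img, mask, rg.LogRange(2.0), roi_name="toy", erosion_px=0)
        sel = img[1:4, 1:4]
        assert st.n_pixels == 9
        assert st.log10_min == pytest.approx(np.log10(0.01))
        assert st.log10_max == pytest.approx(np.log10(0.8))
        assert st.log10_mean == pytest.approx(np.log10(sel / 1.0).mean())
        assert st.percent_min == pytest.approx(100 * (1 + np.log10(0.01) / 2.0))
        assert st.linear_mean == pytest.approx(sel.mean())

    def test_uniform_roi_collapses(self):
        img = np.full((8, 8), 0.3)
        img[0, 0] = 1.0
        mask = np.zeros((8, 8), bool)
        mask[4:7, 4:7] = True
        st = rg.roi_stats(img, mask, erosion_px=0)
        assert st.log10_min == st.log10_max == st.log10_mean

    def test_erosion_drops_border_pixels(self):
        img = np.ones((9, 9))
        img[4, 4] = 0.5  # interior value differs from the rim of the ROI
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        full = rg.roi_stats(img, mask, erosion_px=0)
        eroded = rg.roi_stats(img, mask, erosion_px=2)
        assert eroded.n_pixels == 1
        assert eroded.linear_mean == 0.5
        assert full.n_pixels == 25

    def test_erosion_falls_back_when_mask_vanishes(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        st = rg.roi_stats(np.ones((8, 8)), mask, erosion_px=2)
        assert st.n_pixels == 1 and st.erosion_px == 0

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            rg.roi_stats(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rg.roi_stats(np.ones((4, 4)), np.zeros((5, 5), bool))


class TestImageRange:
    def test_two_level_image(self):
        img = np.array([[1.0, 0.1]])
        assert rg.image_range(img, rg.LogRange(2.0)) == pytest.approx(50.0)

    def test_clipped_at_hundred(self):
        img = np.array([[1.0, 1e-9]])
        assert rg.image_range(img, rg.LogRange(2.3)) == 100.0

    def test_positive_required(self):
        with pytest.raises(ValueError):
            rg.image_range(np.array([[0.0, 1.0]]))


class TestHistogram:
    def test_two_level_map_occupies_two_log_bins(self):
        b = rg.make_centered_square(257, 75)
        scene = b.scene_luminance()
        h = rg.histogram(scene, "log")
        assert (h.counts > 0).sum() == 2
        assert h.normalized_counts.max() == 1.0
        assert len(h.bin_edges) == 257

    def test_tally_oracle_linear(self, rng):
        img = rng.uniform(0.01, 1.0, (8, 8))
        img.flat[0] = 1.0
        h = rg.histogram(img, "linear")
        # direct per-pixel tally
        tally = np.zeros(256, int)
        for v in img.ravel():
            idx = min(int(v / (1.0 / 256)), 255)
            tally[idx] += 1
        np.testing.assert_array_equal(h.counts, tally)

    def test_log_mode_clips_below_floor_into_lowest_bin(self):
        img = np.array([[1.0, 1e-6, 1e-6, 0.5]])
        h = rg.histogram(img, "log", rg.LogRange(2.3))
        assert h.counts[0] == 2
        assert h.counts.sum() == 4

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            rg.histogram(np.ones((2, 2)), "sqrt")


class TestScan:
    def test_values_equal_direct_indexing(self, rng):
        scene = rng.uniform(0.01, 1.0, (6, 10))
        retina = rng.uniform(0.01, 1.0, (6, 10))
        p = rg.scan(scene, retina, 3)
        np.testing.assert_allclose(p.scene_log10, np.log10(scene[3] / scene.max()))
        np.testing.assert_allclose(p.retina_log10, np.log10(retina[3] / retina.max()))
        assert p.scene_log10.shape == (10,)

    def test_out_of_range_row(self):
        with pytest.raises(ValueError):
            rg.scan(np.ones((4, 4)), np.ones((4, 4)), 7)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rg.scan(np.ones((4, 4)), np.ones((5, 4)), 1)


def _toy_bundle(order):
    rois = {
        "left": np.zeros((6, 6), bool),
        "right": np.zeros((6, 6), bool),
    }
    rois["left"][1:3, 1:3] = True
    rois["right"][1:3, 4:6] = True
    return TargetBundle(
        map=DigitMap(np.full((6, 6), 100, np.uint8)),
        calibration=DisplayCalibration(((0, 1.0), (255, 100.0))),
        rois=rois,
        appearance_order=order,
        geometry=AngularGeometry((6, 6), 1.0),
        metadata={},
    )


class TestParadoxReport:
    def test_darker_roi_with_more_light_is_a_paradox(self):
        retina = np.full((6, 6), 0.2)
        retina[1:3, 1:3] = 0.5  # 'left' gets more light
        reports = rg.paradox_report(retina, _toy_bundle([("left", "right")]), erosion_px=0)
        assert reports[0].paradox is True
        assert reports[0].mean_darker == pytest.approx(0.5)

    def test_equal_means_are_not_a_paradox(self):
        reports = rg.paradox_report(
            np.full((6, 6), 0.3), _toy_bundle([("left", "right")]), erosion_px=0
        )
        assert reports[0].paradox is False

    def test_one_report_per_declared_pair(self):
        reports = rg.paradox_report(
            np.full((6, 6), 0.3),
            _toy_bundle([("left", "right"), ("right", "left")]),
            erosion_px=0,
        )
        assert len(reports) == 2

    def test_missing_roi_error(self):
        with pytest.raises(KeyError):
            rg.paradox_report(np.ones((6, 6)), _toy_bundle([("left", "ghost")]))
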