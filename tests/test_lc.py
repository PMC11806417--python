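"""LC contrast pipeline: slice correction, tripartition, brightest cluster."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from brainstemnm.core import RoiMask, RoiStats, roi_stats
from brainstemnm.lc import (
    LcConfig,
    brightest_cluster,
    lc_contrast,
    lc_summarize,
    slice_intensity_correct,
    tripartition,
)
from .conftest import block_mask, make_volume
from .oracles import best_connected_subset_mean, plant_random_connected_cluster


class TestSliceCorrection:
    def test_uniform_reference_is_fixed_point(self, rng):
        vol = make_volume(np.full((6, 6, 4), 50.0) + 0.0)
        ref = block_mask("ref", 1, 5, 1, 5, 0, 4)
        out = slice_intensity_correct(vol, ref)
        np.testing.assert_allclose(out.data, vol.data)

    def test_two_slice_scale_factors(self):
        vol = make_volume(np.zeros((4, 4, 2)))
        vol.data[:, :, 0] = 90.0
        vol.data[:, :, 1] = 110.0
        ref = block_mask("ref", 0, 4, 0, 4, 0, 2)
        out = slice_intensity_correct(vol, ref)
        np.testing.assert_allclose(out.data[:, :, 0], 90 * 100 / 90)
        np.testing.assert_allclose(out.data[:, :, 1], 110 * 100 / 110)

    def test_planted_contrast_preserved(self, rng):
        vol = make_volume(np.full((8, 8, 3), 100.0))
        vol.data[:, :, 1] *= 1.2  # slice gain drift
        vol.data[2, 2, 1] = 108.0 * 1.2  # LC voxel at 8% contrast within its slice
        ref_vox = [(i, j, k) for i in range(5, 8) for j in range(5, 8) for k in range(3)]
        out = slice_intensity_correct(vol, RoiMask("ref", ref_vox, "g"))
        slice_bg = out.data[6, 6, 1]
        assert out.data[2, 2, 1] / slice_bg == pytest.approx(1.08)


class TestTripartition:
    def test_divisible_span(self):
        roi = block_mask("lc", 0, 2, 0, 2, 2, 11)  # 9 slices
        secs = tripartition(roi, 3)
        assert [len(s.slices) for s in secs] == [3, 3, 3]
        # rostral = superior (highest k)
        assert set(secs[0].slices) == {8, 9, 10}
        assert set(secs[2].slices) == {2, 3, 4}

    def test_remainder_goes_rostral_first(self):
        roi = block_mask("lc", 0, 2, 0, 2, 0, 7)  # 7 slices
        secs = tripartition(roi, 3)
        assert [len(s.slices) for s in secs] == [3, 2, 2]
        assert set(secs[0].slices) == {4, 5, 6}

    def test_single_section_is_identity(self):
        roi = block_mask("lc", 0, 2, 0, 2, 0, 5)
        (sec,) = tripartition(roi, 1)
        np.testing.assert_array_equal(sec.voxels, roi.voxels)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="slices"):
            tripartition(block_mask("lc", 0, 2, 0, 2, 0, 2), 3)

    @given(n_slices=st.integers(3, 13), n_sections=st.integers(1, 3))
    def test_disjoint_cover_with_balanced_sizes(self, n_slices, n_sections):
        roi = block_mask("lc", 0, 2, 0, 3, 0, n_slices)
        secs = tripartition(roi, n_sections)
        sizes = [len(s.slices) for s in secs]
        assert max(sizes) - min(sizes) <= 1
        all_vox = np.vstack([s.voxels for s in secs])
        assert all_vox.shape[0] == len(roi)
        assert len({tuple(v) for v in all_vox}) == len(roi)


class TestBrightestCluster:
    def test_constant_roi_returns_constant_mean(self):
        vol = make_volume(np.full((5, 5, 3), 42.0))
        mean, cluster = brightest_cluster(vol, block_mask("r", 0, 5, 0, 5, 0, 3), LcConfig())
        assert mean == 42.0 and cluster.shape == (5, 3)

    def test_planted_dominant_cluster_found_exactly(self):
        vol = make_volume(np.full((8, 8, 3), 100.0))
        planted = np.array([(3, 3, 1), (4, 3, 1), (3, 4, 1), (2, 3, 1), (3, 2, 1)])
        vol.data[planted[:, 0], planted[:, 1], planted[:, 2]] = 200.0
        mean, cluster = brightest_cluster(vol, block_mask("r", 0, 8, 0, 8, 0, 3), LcConfig())
        assert mean == 200.0
        assert {tuple(v) for v in cluster} == {tuple(v) for v in planted}

    def test_greedy_mean_at_least_roi_mean(self, rng):
        vol = make_volume(rng.normal(100, 5, (6, 6, 2)))
        roi = block_mask("r", 0, 6, 0, 6, 0, 2)
        mean, _ = brightest_cluster(vol, roi, LcConfig())
        assert mean >= np.mean(roi.values(vol))

    def test_small_roi_rejected(self):
        vol = make_volume(np.zeros((3, 3, 1)))
        with pytest.raises(ValueError, match="n_cluster"):
            brightest_cluster(vol, RoiMask("r", [(0, 0, 0), (1, 1, 0)], "g"), LcConfig())

    def test_fragmented_roi_rejected(self):
        # two disconnected 3-voxel islands: no connected 5-subset exists
        vol = make_volume(np.zeros((10, 3, 1)))
        vox = [(0, 0, 0), (0, 1, 0), (0, 2, 0), (8, 0, 0), (8, 1, 0), (8, 2, 0)]
        with pytest.raises(ValueError, match="connected component"):
            brightest_cluster(vol, RoiMask("r", vox, "g"), LcConfig())

    def test_matches_exhaustive_oracle_on_random_fixtures(self, rng):
        for _ in range(15):
            vol = make_volume(rng.normal(100, 3, (3, 3, 2)))
            roi = block_mask("r", 0, 3, 0, 3, 0, 2)  # 18 voxels
            planted = plant_random_connected_cluster(rng, roi.voxels, n=5)
            for v in planted:  # unique dominant cluster, excess >> noise
                vol.data[v] += 50
            mean, cluster = brightest_cluster(vol, roi, LcConfig())
            oracle = best_connected_subset_mean(vol.data, roi.voxels, n=5)
            assert mean == pytest.approx(oracle)
            assert {tuple(v) for v in cluster} == set(planted)

    def test_deterministic_tie_break(self):
        vol = make_volume(np.full((4, 4, 1), 10.0))
        _, c1 = brightest_cluster(vol, block_mask("r", 0, 4, 0, 4, 0, 1), LcConfig())
        _, c2 = brightest_cluster(vol, block_mask("r", 0, 4, 0, 4, 0, 1), LcConfig())
        np.testing.assert_array_equal(c1, c2)


class TestContrast:
    def test_zero_when_equal(self):
        assert lc_contrast(100.0, RoiStats(100.0, 1.0, 50)) == 0.0

    def test_hand_arithmetic(self):
        assert lc_contrast(105.0, RoiStats(100.0, 1.0, 50)) == pytest.approx(0.05)

    def test_negative_contrast_allowed(self):
        assert lc_contrast(99.49, RoiStats(100.0, 1.0, 50)) == pytest.approx(-0.0051)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            lc_contrast(10.0, RoiStats(0.0, 1.0, 50))

    def test_scale_invariance(self, rng):
        vol = make_volume(rng.normal(100, 2, (6, 6, 3)))
        roi = block_mask("lc", 0, 3, 0, 3, 0, 3)
        bgm = block_mask("bg", 3, 6, 3, 6, 0, 3)
        mean, _ = brightest_cluster(vol, roi, LcConfig())
        c1 = lc_contrast(mean, roi_stats(vol, bgm))
        scaled = make_volume(vol.data * 3.7)
        mean2, _ = brightest_cluster(scaled, roi, LcConfig())
        c2 = lc_contrast(mean2, roi_stats(scaled, bgm))
        assert c1 == pytest.approx(c2)


class TestSummarize:
    def _cells(self, over=None):
        cells = {(s, sec): 0.05 for s in ("left", "right") for sec in ("rostral", "middle", "caudal")}
        cells.update(over or {})
        return cells

    def test_equal_sides(self):
        c = lc_summarize(self._cells(), 100.0)
        assert c.rostral == c.middle == c.caudal == 0.05

    def test_hand_arithmetic(self):
        c = lc_summarize(self._cells({("left", "middle"): 0.06, ("right", "middle"): 0.04}), 100.0)
        assert c.middle == pytest.approx(0.05)

    def test_side_swap_invariance(self):
        a = lc_summarize(self._cells({("left", "caudal"): 0.02, ("right", "caudal"): 0.08}), 100.0)
        b = lc_summarize(self._cells({("left", "caudal"): 0.08, ("right", "caudal"): 0.02}), 100.0)
        assert a.caudal == b.caudal

    def test_missing_cell_rejected(self):
        cells = self._cells()
        del cells[("left", "middle")]
        with pytest.raises(ValueError, match="missing"):
            lc_summarize(cells, 100.0)
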