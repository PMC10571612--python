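"""Imaging metrics against voxel-count, moment and exhaustive-search oracles."""

import numpy as np
import pytest
from skimage import draw, morphology

import pchsim.imaging as im
from pchsim.imaging import VoxelImage


def _two_blob_volume():
    vol = np.full((24, 24, 24), 10.0)
    vol[4:8, 4:8, 4:8] = 200.0
    vol[14:19, 14:19, 14:19] = 200.0
    return VoxelImage(channels={"a": vol})


class TestSegmentChannel:
    def test_two_level_image_threshold_between_levels(self):
        seg = im.segment_channel(_two_blob_volume(), "a")
        assert 10.0 < seg.threshold < 200.0
        assert seg.n_objects == 2

    def test_otsu_equals_exhaustive_between_class_variance(self, rng):
        """Otsu via the library matches brute-force variance maximization."""
        img = np.clip(rng.normal(80, 20, (40, 40)), 0, 255)
        img[10:25, 5:30] += 100
        img = img.astype(np.uint8)
        seg = im.segment_channel(VoxelImage(channels={"a": img}), "a")
        best, best_t = -1.0, 0
        flat = img.ravel().astype(float)
        for t in range(1, 256):
            lo, hi = flat[flat < t], flat[flat >= t]
            if len(lo) == 0 or len(hi) == 0:
                continue
            w = len(lo) * len(hi) / len(flat) ** 2
            v = w * (lo.mean() - hi.mean()) ** 2
            if v > best:
                best, best_t = v, t
        # library threshold is the bin below which pixels are background
        assert abs(seg.threshold - (best_t - 1)) <= 1.0

    def test_constant_image_raises(self):
        with pytest.raises(im.DegenerateHistogramError):
            im.segment_channel(VoxelImage(channels={"a": np.ones((8, 8, 8))}), "a")

    def test_fixed_threshold(self):
        seg = im.segment_channel(_two_blob_volume(), "a", method="fixed",
                                 threshold=100.0)
        assert seg.threshold == 100.0 and seg.n_objects == 2

    def test_background_subtraction_removes_gradient(self):
        y = np.linspace(0, 120, 64)
        vol = np.tile(y[None, :, None], (8, 1, 64))
        vol[:, 30:34, 30:34] += 200  # 8x4x4 spot on a strong ramp
        img = VoxelImage(channels={"a": vol})
        raw = im.segment_channel(img, "a")
        sub = im.segment_channel(img, "a", background_radius=6)
        # without subtraction the bright half of the ramp is foreground;
        # with it, an object of exactly the spot's size sits at the spot
        assert raw.table["voxels"].max() > 10 * 128
        spot = sub.table[sub.table["voxels"] == 128]
        assert len(spot) == 1
        row = spot.iloc[0]
        assert 30 <= row["centroid_y"] <= 34 and 30 <= row["centroid_x"] <= 34


class TestShellOccupancy:
    def test_full_and_empty_cover(self):
        nuc = np.zeros((20, 20, 20), bool)
        nuc[8:12, 8:12, 8:12] = True
        everything = np.ones_like(nuc)
        assert im.shell_occupancy(nuc, everything, 1) == 1.0
        assert im.shell_occupancy(nuc, np.zeros_like(nuc), 1) == 0.0

    def test_hemispherical_cap_matches_voxel_count(self):
        z, y, x = np.indices((40, 40, 40))
        nuc = (z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 8 ** 2
        target = z > 20  # half-space target
        occ = im.shell_occupancy(nuc, target, 2)
        shell = (np.array((z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2)
                 <= 10 ** 2)  # oracle shell via dilation below
        from scipy import ndimage as ndi
        oshell = ndi.binary_dilation(nuc, morphology.ball(2)) & ~nuc
        expected = (oshell & target).sum() / oshell.sum()
        assert occ == pytest.approx(expected, abs=1e-12)
        assert occ == pytest.approx(0.5, abs=0.05)

    def test_monotone_in_target_dilation(self):
        rng = np.random.default_rng(0)
        nuc = np.zeros((24, 24, 24), bool)
        nuc[10:14, 10:14, 10:14] = True
        tgt = rng.random((24, 24, 24)) > 0.9
        from scipy import ndimage as ndi
        occ = [im.shell_occupancy(
            nuc, ndi.binary_dilation(tgt, morphology.ball(k)) if k else tgt,
            1) for k in range(3)]
        assert occ[0] <= occ[1] <= occ[2]

    def test_empty_nucleolus_rejected(self):
        with pytest.raises(ValueError):
            im.shell_occupancy(np.zeros((5, 5, 5), bool),
                               np.ones((5, 5, 5), bool), 1)


def _objects_from_mask(mask, voxel_size=(0.1, 0.1, 0.1)):
    from skimage import measure
    from pchsim.imaging import SegmentedObjects, _label_table
    labels = measure.label(mask, connectivity=mask.ndim)
    return SegmentedObjects(labels=labels, voxel_size=voxel_size,
                            table=_label_table(labels))


class TestNearestObjectDistance:
    def test_identical_single_objects(self):
        m = np.zeros((10, 10, 10), bool)
        m[3:5, 3:5, 3:5] = True
        a = _objects_from_mask(m)
        d = im.nearest_object_distance(a, _objects_from_mask(m.copy()))
        assert d == pytest.approx([0.0])

    def test_ten_voxels_at_point_one_micron(self):
        m1 = np.zeros((20, 20, 20), bool)
        m2 = np.zeros_like(m1)
        m1[5, 5, 2] = True
        m2[5, 5, 12] = True
        d = im.nearest_object_distance(_objects_from_mask(m1),
                                       _objects_from_mask(m2))
        assert d == pytest.approx([1.0])

    def test_matches_brute_force_all_pairs(self, rng):
        a = np.zeros((30, 30, 30), bool)
        b = np.zeros_like(a)
        for arr, k in ((a, 6), (b, 5)):
            for _ in range(k):
                z, y, x = rng.integers(2, 27, 3)
                arr[z, y, x] = True
        oa, ob = _objects_from_mask(a, (0.2, 0.1, 0.1)), _objects_from_mask(b, (0.2, 0.1, 0.1))
        d = im.nearest_object_distance(oa, ob)
        ca, cb = oa.centroids_um(), ob.centroids_um()
        expected = np.sqrt(((ca[:, None] - cb[None]) ** 2).sum(-1)).min(1)
        assert np.allclose(np.sort(d), np.sort(expected))

    def test_empty_b_warns(self):
        m = np.zeros((8, 8, 8), bool)
        m[2, 2, 2] = True
        with pytest.warns(UserWarning):
            d = im.nearest_object_distance(_objects_from_mask(m),
                                           _objects_from_mask(np.zeros_like(m)))
        assert len(d) == 0


class TestAspectRatio:
    def test_disk_is_round(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw.disk((32, 32), 20)
        mask[rr, cc] = True
        assert im.aspect_ratio_2d(mask) == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = draw.ellipse(64, 64, 20, 40)
        mask[rr, cc] = True
        assert im.aspect_ratio_2d(mask) == pytest.approx(2.0, rel=0.05)

    def test_rotation_invariance(self):
        from scipy import ndimage as ndi
        mask = np.zeros((160, 160), bool)
        rr, cc = draw.ellipse(80, 80, 18, 42)
        mask[rr, cc] = True
        rot = ndi.rotate(mask.astype(float), 37.0, reshape=True, order=1) > 0.5
        assert im.aspect_ratio_2d(rot) == pytest.approx(
            im.aspect_ratio_2d(mask), rel=0.02)

    def test_degenerate_line_flagged(self):
        mask = np.zeros((32, 32), bool)
        mask[16, 4:28] = True
        with pytest.warns(UserWarning):
            r = im.aspect_ratio_2d(mask)
        assert r >= 1.0


class TestObjectTimeseries:
    def _series(self, n=4, bleach=0.0, side=12):
        imgs = []
        for t in range(n):
            arr = np.full((6, 48, 48), 15.0)
            amp = 180.0 * np.exp(-bleach * t)
            arr[:, 18:18 + side, 18:18 + side] += amp
            imgs.append(VoxelImage(channels={"p": arr}))
        return imgs

    def test_constant_series_normalizes_to_one(self):
        df = im.object_timeseries(self._series(), "p")
        assert np.allclose(df["norm_intensity"], 1.0)
        assert df["norm_intensity"].iloc[0] == 1.0

    def test_bleaching_decay_recovered(self):
        df = im.object_timeseries(self._series(bleach=0.3), "p")
        assert np.all(np.diff(df["norm_intensity"]) < 0)

    def test_disk_circularity_near_one(self):
        arr = np.full((4, 80, 80), 10.0)
        rr, cc = draw.disk((40, 40), 18)
        arr[:, rr, cc] += 150
        df = im.object_timeseries([VoxelImage(channels={"p": arr})], "p")
        assert df["circularity"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_square_circularity_matches_estimator_oracle(self):
        from skimage import measure
        df = im.object_timeseries(self._series(n=1, side=14), "p")
        mask = np.zeros((48, 48), bool)
        mask[18:32, 18:32] = True
        oracle = 4 * np.pi * mask.sum() / measure.perimeter_crofton(
            mask, directions=4) ** 2
        assert df["circularity"].iloc[0] == pytest.approx(oracle, rel=1e-6)
        # a square is measurably less circular than the disk case (~1.0)
        assert df["circularity"].iloc[0] < 0.95

    def test_vanishing_segment_recorded_as_gap(self):
        imgs = self._series(n=3)
        imgs[1] = VoxelImage(channels={"p": np.full((6, 48, 48), 15.0)})
        df = im.object_timeseries(imgs, "p")
        assert np.isnan(df["area_px"].iloc[1])
        assert np.isfinite(df["area_px"].iloc[2])


class TestLineProfile:
    def _image(self):
        z, y, x = np.indices((5, 40, 40), dtype=float)
        spot = 100 * np.exp(-((y - 20) ** 2 + (x - 25) ** 2) / 18.0)
        flat = np.full((5, 40, 40), 7.0)
        return VoxelImage(channels={"g": spot, "m": flat})

    def test_each_channel_max_is_one(self):
        pos, traces = im.line_profile(self._image(), (2, 20, 0), (2, 20, 39))
        assert traces["g"].max() == pytest.approx(1.0)
        assert np.allclose(traces["m"], 1.0)

    def test_gaussian_peak_location(self):
        pos, traces = im.line_profile(self._image(), (2, 20, 0), (2, 20, 39),
                                      channels=["g"])
        # peak should sit at x=25 -> index 25 of 40 samples, within one voxel
        assert abs(np.argmax(traces["g"]) - 25) <= 1

    def test_zero_profile_unscaled_with_warning(self):
        img = VoxelImage(channels={"g": np.zeros((4, 8, 8))})
        with pytest.warns(UserWarning):
            _, traces = im.line_profile(img, (1, 1, 1), (1, 6, 6))
        assert traces["g"].max() == 0.0

    def test_endpoint_outside_rejected(self):
        with pytest.raises(ValueError):
            im.line_profile(self._image(), (0, 0, 0), (0, 0, 100))


class TestObjectVolume:
    def test_thousand_voxels_at_point_one_micron(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:10, :10, :10] = True  # exactly 1000 voxels
        vols = im.object_volume(_objects_from_mask(mask))
        assert vols.iloc[0] == pytest.approx(1.0)

    def test_empty_labels_absent(self):
        vols = im.object_volume(_objects_from_mask(np.zeros((5, 5, 5), bool)))
        assert len(vols) == 0

    def test_digitized_sphere_within_three_percent(self):
        z, y, x = np.indices((30, 30, 30))
        mask = (z - 15) ** 2 + (y - 15) ** 2 + (x - 15) ** 2 <= 10 ** 2
        vols = im.object_volume(_objects_from_mask(mask, (1.0, 1.0, 1.0)))
        assert vols.iloc[0] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.03)


class TestVoxelImageValidation:
    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            VoxelImage(channels={"a": np.zeros((4, 4, 4)),
                                 "b": np.zeros((5, 4, 4))})

    def test_bad_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            VoxelImage(channels={"a": np.zeros((4, 4, 4))},
                       voxel_size=(0.1, 0.0, 0.1))
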