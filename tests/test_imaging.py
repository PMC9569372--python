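import numpy as np
import pytest
from skimage.draw import disk

from regforest import imaging
from regforest.imaging import (LabeledVolume, ZStack, coloc_ratio,
                               filter_small, fraction_high, link_z,
                               measure_nuclei, nuclear_correlation,
                               segment_plane, segment_stack,
                               spheroid_projected_area, split_touching)
from regforest.synthetic import gen_confocal_stack


def disc_image(shape, centers, radius_px, fg=200.0, bg=10.0):
    img = np.full(shape, bg)
    for c in centers:
        rr, cc = disk(c, radius_px, shape=shape)
        img[rr, cc] = fg
    return img


class TestSegmentPlane:
    def test_bimodal_disc_recovered_exactly(self):
        img = disc_image((128, 128), [(64, 64)], 20)
        mask = segment_plane(img)
        assert np.array_equal(mask, img > 100)

    def test_constant_plane_gives_empty_mask(self):
        assert not segment_plane(np.full((64, 64), 37.0)).any()

    def test_gradient_background_with_blobs(self):
        """Local thresholding rejects a bright illumination gradient."""
        yy, xx = np.mgrid[0:256, 0:256]
        img = 120.0 * xx / 255.0  # background ramp 0..120
        truth = np.zeros((256, 256), bool)
        for c in [(64, 64), (192, 200)]:
            rr, cc = disk(c, 8, shape=img.shape)
            img[rr, cc] = 200.0
            truth[rr, cc] = True
        mask = segment_plane(img, block_size_px=32)
        jac = (mask & truth).sum() / (mask | truth).sum()
        assert jac >= 0.9

    def test_small_block_size_rejected(self):
        with pytest.raises(ValueError):
            segment_plane(np.zeros((32, 32)), block_size_px=4)


class TestSplitTouching:
    def test_single_disc_one_label(self):
        mask = disc_image((128, 128), [(64, 64)], 16, fg=1, bg=0) > 0
        labels = split_touching(mask, pixel_size_xy=0.3)
        assert labels.max() == 1

    def test_overlapping_pair_split_with_correct_centroid_gap(self):
        ps = 0.3
        gap_px = 10.0 / ps  # centers 10 um apart, radii 5 um -> overlap
        c1, c2 = (100.0, 80.0), (100.0, 80.0 + gap_px)
        mask = disc_image((200, 200), [c1, c2], 5.0 / ps, fg=1, bg=0) > 0
        labels = split_touching(mask, pixel_size_xy=ps)
        assert labels.max() == 2
        from skimage.measure import regionprops
        cents = [np.array(rp.centroid) for rp in regionprops(labels)]
        gap_um = np.linalg.norm(cents[0] - cents[1]) * ps
        assert gap_um == pytest.approx(10.0, abs=1.5)

    def test_empty_mask_zero_labels(self):
        assert split_touching(np.zeros((32, 32), bool), 0.3).max() == 0


class TestLinkZ:
    @staticmethod
    def drifting_planes(drift_um_per_plane, n=6, ps=0.3):
        planes = []
        for z in range(n):
            img = np.zeros((128, 128), np.int32)
            rr, cc = disk((40 + drift_um_per_plane * z / ps, 64), 4.0 / ps,
                          shape=img.shape)
            img[rr, cc] = 1
            planes.append(img)
        return planes

    def test_stationary_disc_links_into_one_nucleus(self):
        vol = link_z(self.drifting_planes(0.0, n=5), 0.3, 1.0)
        assert len(vol.label_ids) == 1

    def test_lateral_offset_beyond_threshold_stays_separate(self):
        planes = []
        for z in range(4):
            img = np.zeros((128, 128), np.int32)
            rr, cc = disk((40, 50), 10, shape=img.shape)
            img[rr, cc] = 1
            rr, cc = disk((40, 50 + 5.0 / 0.3), 10, shape=img.shape)
            img[rr, cc] = 2
            planes.append(img)
        vol = link_z(planes, 0.3, 1.0)
        assert len(vol.label_ids) == 2

    def test_slow_drift_links_fast_drift_breaks(self):
        slow = link_z(self.drifting_planes(0.5), 0.3, 1.0)
        fast = link_z(self.drifting_planes(2.0), 0.3, 1.0)
        assert len(slow.label_ids) == 1
        assert len(fast.label_ids) == 6  # chain broken at every step


class TestFilterSmall:
    @staticmethod
    def volume_with_sizes(*voxel_counts):
        # 1x1x1 um voxels: voxel count == volume in um^3
        arr = np.zeros((len(voxel_counts), 20, 50), np.int32)
        for i, n in enumerate(voxel_counts):
            arr[i].flat[:n] = i + 1
        return LabeledVolume(arr, pixel_size_xy=1.0, z_step=1.0)

    def test_threshold_boundary_rules(self):
        vol = self.volume_with_sizes(50, 150, 100)
        kept = filter_small(vol)
        surviving = {int(c) for c in np.bincount(kept.labels.ravel())[1:] if c}
        # 50 um^3 removed, 150 kept, exactly 100 kept (strict less-than)
        assert surviving == {150, 100}
        assert list(kept.label_ids) == [1, 2]  # relabeled contiguously

    def test_idempotent_and_never_grows(self):
        vol = self.volume_with_sizes(40, 120, 300)
        once = filter_small(vol)
        twice = filter_small(once)
        assert np.array_equal(once.labels, twice.labels)
        assert (once.labels > 0).sum() <= (vol.labels > 0).sum()


class TestMeasure:
    def test_painted_nuclei_recovered_exactly(self):
        labels = np.zeros((4, 10, 10), np.int32)
        labels[1, 2:5, 2:5] = 1
        labels[2, 6:9, 6:9] = 2
        marker = np.zeros((4, 10, 10), np.float32)
        marker[labels == 1] = 100.0
        marker[labels == 2] = 400.0
        stack = ZStack(data=marker[None], pixel_size_xy=0.5, z_step=1.0,
                       channels=["marker"])
        vol = LabeledVolume(labels, pixel_size_xy=0.5, z_step=1.0)
        m1, m2 = measure_nuclei(vol, stack)
        assert m1.mean_intensity["marker"] == pytest.approx(100.0)
        assert m2.mean_intensity["marker"] == pytest.approx(400.0)
        assert m1.volume_um3 == pytest.approx(9 * 0.25)  # 9 voxels x 0.25 um^3

    def test_geometry_mismatch_rejected(self):
        stack = ZStack(data=np.zeros((1, 2, 4, 4)), pixel_size_xy=0.5,
                       z_step=1.0, channels=["c"])
        vol = LabeledVolume(np.zeros((3, 4, 4), np.int32), 0.5, 1.0)
        with pytest.raises(ValueError):
            measure_nuclei(vol, stack)

    def test_intensity_scale_invariance_of_segmentation(self):
        stack, _ = gen_confocal_stack(n_nuclei=4, noise_sd=0.0, seed=7,
                                      shape_um=(20.0, 50.0, 50.0))
        v1 = segment_stack(stack)
        scaled = ZStack(data=stack.data * 3.0, pixel_size_xy=stack.pixel_size_xy,
                        z_step=stack.z_step, channels=stack.channels)
        v2 = segment_stack(scaled)
        assert np.array_equal(v1.labels, v2.labels)


class TestSummaries:
    @staticmethod
    def measurements(means, channel="oct4"):
        out = []
        for i, m in enumerate(means, start=1):
            out.append(imaging.NucleusMeasurement(
                label=i, volume_um3=200.0, centroid_um=(0, 0, 0),
                mean_intensity={channel: m} if not isinstance(m, dict) else m))
        return out

    def test_fraction_high(self):
        ms = self.measurements([100.0, 400.0, 500.0])
        assert fraction_high(ms, "oct4", 300.0) == pytest.approx(2 / 3)
        assert fraction_high(self.measurements([10.0, 20.0]), "oct4") == 0.0
        # exactly at threshold is not "high"
        assert fraction_high(self.measurements([300.0]), "oct4") == 0.0
        with pytest.raises(ValueError):
            fraction_high([], "oct4")

    def test_nuclear_correlation_limits_and_hand_value(self):
        a = [100.0, 200.0, 300.0, 400.0, 500.0]
        b = [120.0, 180.0, 320.0, 360.0, 520.0]
        ms = self.measurements([{"x": x, "y": y} for x, y in zip(a, b)])
        assert nuclear_correlation(ms, "x", "x") == pytest.approx(1.0)
        neg = self.measurements([{"x": x, "y": 600.0 - x} for x in a])
        assert nuclear_correlation(neg, "x", "y") == pytest.approx(-1.0)
        expected = float(np.corrcoef(a, b)[0, 1])
        assert nuclear_correlation(ms, "x", "y") == pytest.approx(expected,
                                                                  abs=1e-12)
        flat = self.measurements([{"x": x, "y": 5.0} for x in a])
        with pytest.raises(ValueError):
            nuclear_correlation(flat, "x", "y")


class TestColoc:
    @staticmethod
    def painted_stack(fg_a, fg_b):
        labels = np.zeros((1, 10, 10), np.int32)
        labels[0, 1:9, 1:9] = 1
        a = np.where(fg_a, 500.0, 10.0)
        b = np.where(fg_b, 500.0, 10.0)
        stack = ZStack(data=np.stack([a, b]), pixel_size_xy=1.0, z_step=1.0,
                       channels=["a", "b"])
        return LabeledVolume(labels, 1.0, 1.0), stack

    def test_identical_foregrounds_give_one(self):
        fg = np.zeros((1, 10, 10), bool)
        fg[0, 1:9, 1:5] = True
        vol, stack = self.painted_stack(fg, fg)
        ratios = coloc_ratio(vol, stack, ["a", "b"])
        # half the nucleus is jointly foreground in both channels
        assert ratios[1] == pytest.approx(0.5)
        # identical whole-nucleus foreground -> ratio 1 requires bg contrast
        fg_full = np.zeros((1, 10, 10), bool)
        fg_full[0, 1:9, 1:9] = True
        fg_full[0, 1, 1] = False  # one bg voxel keeps Otsu non-degenerate
        vol2, stack2 = self.painted_stack(fg_full, fg_full)
        assert coloc_ratio(vol2, stack2, ["a", "b"])[1] == pytest.approx(
            63 / 64)

    def test_disjoint_foregrounds_give_zero(self):
        fa = np.zeros((1, 10, 10), bool)
        fb = np.zeros((1, 10, 10), bool)
        fa[0, 1:9, 1:4] = True
        fb[0, 1:9, 6:9] = True
        vol, stack = self.painted_stack(fa, fb)
        assert coloc_ratio(vol, stack, ["a", "b"])[1] == 0.0

    def test_constant_channel_warns_and_reports_zero(self):
        fg = np.zeros((1, 10, 10), bool)
        fg[0, 1:9, 1:5] = True
        vol, stack = self.painted_stack(fg, np.zeros((1, 10, 10), bool))
        with pytest.warns(UserWarning, match="constant"):
            ratios = coloc_ratio(vol, stack, ["a", "b"])
        assert ratios[1] == 0.0

    def test_bounds(self):
        stack, _ = gen_confocal_stack(
            n_nuclei=3, seed=2, shape_um=(20.0, 50.0, 50.0),
            channel_intensity_map={"m1": (100, 500), "m2": (100, 500)})
        vol = segment_stack(stack)
        ratios = coloc_ratio(vol, stack, ["m1", "m2"])
        assert all(0.0 <= r <= 1.0 for r in ratios.values())


class TestSpheroidArea:
    def test_filled_rectangle(self):
        img = np.full((300, 300), 5.0)
        img[50:150, 40:240] = 200.0  # 100 x 200 px
        assert spheroid_projected_area(img, 0.5) == pytest.approx(5000.0)

    def test_disc_within_three_percent(self):
        img = disc_image((200, 200), [(100, 100)], 30)
        area = spheroid_projected_area(img, 1.0)
        assert area == pytest.approx(np.pi * 30 ** 2, rel=0.03)

    def test_blank_image_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert spheroid_projected_area(np.zeros((64, 64)), 1.0) == 0.0

    def test_largest_component_only_with_hole_filling(self):
        img = np.full((200, 200), 5.0)
        img[20:120, 20:120] = 200.0
        img[60:70, 60:70] = 5.0      # hole, must be filled
        img[150:155, 150:155] = 200.0  # small distractor
        assert spheroid_projected_area(img, 1.0) == pytest.approx(100 * 100)


class TestPipelineRecovery:
    def test_well_separated_nuclei_recovered(self):
        stack, truth = gen_confocal_stack(n_nuclei=12, seed=4)
        vol = segment_stack(stack)
        measured = measure_nuclei(vol, stack)
        assert len(measured) == 12
        tt = truth.table
        vol_errs, pairs = [], []
        for m in measured:
            d = np.sqrt((tt.center_x_um - m.centroid_um[0]) ** 2
                        + (tt.center_y_um - m.centroid_um[1]) ** 2
                        + (tt.center_z_um - m.centroid_um[2]) ** 2)
            i = int(d.idxmin())
            assert d[i] < 2.0  # centroids land on the right nucleus
            pairs.append((m, i))
            vol_errs.append(abs(m.volume_um3 - tt.volume_um3[i])
                            / tt.volume_um3[i])
        assert max(vol_errs) <= 0.15
        r = np.corrcoef([m.mean_intensity["marker"] for m, _ in pairs],
                        [tt.true_marker[i] for _, i in pairs])[0, 1]
        assert r >= 0.95

    def test_noiseless_means_match_painted_values(self):
        """With mild blur the per-nucleus means match the painted values to
        5 %; at the default 0.5 um blur the edge attenuation is larger but
        uniform across nuclei (so relative comparisons stay faithful)."""
        stack, truth = gen_confocal_stack(n_nuclei=5, noise_sd=0.0, seed=6,
                                          shape_um=(22.0, 60.0, 60.0),
                                          blur_sigma_um=0.2)
        vol = segment_stack(stack)
        measured = measure_nuclei(vol, stack)
        assert len(measured) == 5
        tt = truth.table

        def truth_index(m):
            d = np.sqrt((tt.center_x_um - m.centroid_um[0]) ** 2
                        + (tt.center_y_um - m.centroid_um[1]) ** 2
                        + (tt.center_z_um - m.centroid_um[2]) ** 2)
            return int(d.idxmin())

        for m in measured:
            assert m.mean_intensity["marker"] == pytest.approx(
                tt.true_marker[truth_index(m)], rel=0.05)

        stack_d, truth_d = gen_confocal_stack(n_nuclei=5, noise_sd=0.0, seed=6,
                                              shape_um=(22.0, 60.0, 60.0))
        measured_d = measure_nuclei(segment_stack(stack_d), stack_d)
        tt = truth_d.table
        ratios = [m.mean_intensity["marker"] / tt.true_marker[truth_index(m)]
                  for m in measured_d]
        assert all(0.8 <= r <= 1.0 for r in ratios)
        assert np.std(ratios) < 0.05


class TestStackIO:
    def test_tiff_yaml_roundtrip(self, tmp_path):
        stack, _ = gen_confocal_stack(n_nuclei=2, seed=1,
                                      shape_um=(18.0, 40.0, 40.0))
        imaging.write_stack(stack, tmp_path / "s.tif", tmp_path / "s.yaml")
        back = imaging.read_stack(tmp_path / "s.tif", tmp_path / "s.yaml")
        assert back.channels == stack.channels
        assert back.pixel_size_xy == stack.pixel_size_xy
        assert np.allclose(back.data, stack.data)
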