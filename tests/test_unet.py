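"""Segmentation backends: RoI crop, oracle stages, training config."""

import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from chdseg.core import (AO, BACKGROUND, BLOODPOOL_BOUNDARY,
                         BLOODPOOL_CODES, BLOODPOOL_INTERIOR, PA,
                         IntensityVolume, LabelVolume)
from chdseg.unet import (NoHeartFoundError, OracleBackend, TrainConfig, UNet,
                         bloodpool_oracle_classes, crop_roi,
                         majority_downsample, segment_bloodpool_2d,
                         segment_chambers_3d, train_unet, upsample_labels)


class TestMajorityDownsample:
    def test_majority_wins(self):
        lab = np.zeros((4, 4, 4), np.int16)
        lab[:3] = 2                      # 48 of 64 voxels
        out = majority_downsample(lab, (1, 1, 1))
        assert out[0, 0, 0] == 2

    def test_background_loses_ties(self):
        lab = np.zeros((2, 2, 2), np.int16)
        lab[0] = 3                       # 4 vs 4 tie with background
        out = majority_downsample(lab, (1, 1, 1))
        assert out[0, 0, 0] == 3

    def test_foreground_tie_goes_to_lower_code(self):
        lab = np.zeros((2, 2, 2), np.int16)
        lab[0] = 5
        lab[1] = 2                       # 4 vs 4 tie between 5 and 2
        out = majority_downsample(lab, (1, 1, 1))
        assert out[0, 0, 0] == 2

    def test_upsample_round_trip(self):
        lab = np.arange(8, dtype=np.int16).reshape(2, 2, 2) % 6
        up = upsample_labels(lab, (4, 4, 4))
        assert np.array_equal(majority_downsample(up, (2, 2, 2)), lab)


class TestCropRoi:
    def test_roi_contains_all_foreground(self, normal_case):
        backend = OracleBackend(normal_case.truth)
        roi, off = crop_roi(normal_case.image, backend)
        fg = np.argwhere(normal_case.truth.data > 0)
        lo, hi = fg.min(axis=0), fg.max(axis=0)
        for k in range(3):
            assert off[k] <= lo[k]
            assert off[k] + roi.shape[k] > hi[k]

    def test_round_trip_intensities(self, normal_case):
        backend = OracleBackend(normal_case.truth)
        roi, off = crop_roi(normal_case.image, backend)
        v = (3, 5, 7)
        orig = normal_case.image.data[off[0] + v[0], off[1] + v[1], off[2] + v[2]]
        assert roi.data[v] == orig

    def test_all_background_raises(self):
        img = IntensityVolume(np.zeros((48, 48, 48), np.float32))
        truth = LabelVolume(np.zeros((48, 48, 48), np.int16))
        with pytest.raises(NoHeartFoundError):
            crop_roi(img, OracleBackend(truth))


class TestOracleStages:
    def test_chambers_equal_majority_downsampled_truth(self, small_case):
        backend = OracleBackend(small_case.truth, small_case.chambers_truth)
        roi, off = crop_roi(small_case.image, backend)
        lab = segment_chambers_3d(roi, backend)
        sl = tuple(slice(off[k], off[k] + roi.shape[k]) for k in range(3))
        expected = small_case.chambers_truth.data[sl].copy()
        expected[np.isin(expected, (AO, PA))] = BACKGROUND
        assert np.array_equal(lab.data, majority_downsample(expected, (64,) * 3))

    def test_no_great_vessel_codes_in_chambers(self, small_case):
        backend = OracleBackend(small_case.truth, small_case.chambers_truth)
        roi, _ = crop_roi(small_case.image, backend)
        lab = segment_chambers_3d(roi, backend)
        assert not np.isin(lab.data, (AO, PA)).any()

    def test_bloodpool_partition(self, small_case):
        backend = OracleBackend(small_case.truth)
        out = segment_bloodpool_2d(small_case.image, backend)
        union = np.isin(out.data, (BLOODPOOL_INTERIOR, BLOODPOOL_BOUNDARY))
        assert np.array_equal(union, np.isin(small_case.truth.data,
                                             BLOODPOOL_CODES))

    def test_disk_slice_boundary_is_closed_ring(self):
        lab = np.zeros((3, 32, 32), np.int16)
        yy, xx = np.mgrid[:32, :32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 100
        lab[1][disk] = 1                     # LV-coded disk in one slice
        classes = bloodpool_oracle_classes(lab)
        ring = classes[1] == BLOODPOOL_BOUNDARY
        interior = classes[1] == BLOODPOOL_INTERIOR
        assert ring.any() and interior.any()
        # ring is 8-connected and single
        _, n = cc_label(ring, np.ones((3, 3)))
        assert n == 1
        # every interior voxel has all 8 in-slice neighbours in the disk
        from scipy.ndimage import binary_erosion
        assert np.array_equal(interior,
                              binary_erosion(disk, np.ones((3, 3), bool)))

    def test_background_slice_stays_background(self):
        lab = np.zeros((2, 8, 8), np.int16)
        classes = bloodpool_oracle_classes(lab)
        assert (classes == 0).all()


class TestTrainConfig:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_published_schedule_switch(self):
        # 0.0002 for the first half, 0.00002 afterwards
        cfg = TrainConfig(epochs=480)
        total = cfg.resolved_epochs("3D")
        assert total == 480
        assert cfg.learning_rate(1, total) == pytest.approx(2e-4)
        assert cfg.learning_rate(total // 2, total) == pytest.approx(2e-4)
        assert cfg.learning_rate(total // 2 + 1, total) == pytest.approx(2e-5)

    def test_switch_for_odd_totals(self):
        cfg = TrainConfig(epochs=5)
        assert cfg.learning_rate(int(np.ceil(5 / 2)) + 1, 5) == pytest.approx(2e-5)

    def test_default_epochs_by_dimensionality(self):
        assert TrainConfig().resolved_epochs("2D") == 6
        assert TrainConfig().resolved_epochs("3D") == 480

    def test_rates_must_be_positive(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_initial=0.0)


class TestTrainingMachinery:
    def test_2d_training_reduces_loss(self, small_case):
        cfg = TrainConfig(epochs=4, seed=0, lr_initial=5e-3, lr_late=5e-4)
        backend = train_unet([small_case], cfg, "2D",
                             levels=2, base_filters=4)
        assert backend.loss_history[-1] < backend.loss_history[0]
        assert backend.task == "bloodpool2d"

    def test_weights_round_trip(self, tmp_path):
        net = UNet(2, 2, 3, levels=2, base_filters=4, seed=0)
        path = tmp_path / "w.npz"
        net.save(path)
        again = UNet.load(path)
        for k, v in net.params.items():
            assert np.array_equal(v, again.params[k])

    def test_training_is_seeded(self, small_case):
        cfg = TrainConfig(epochs=1, seed=4, lr_initial=1e-3)
        a = train_unet([small_case], cfg, "2D", levels=2, base_filters=4)
        b = train_unet([small_case], cfg, "2D", levels=2, base_filters=4)
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k])

    def test_needs_at_least_one_case(self):
        with pytest.raises(ValueError):
            train_unet([], TrainConfig(epochs=1), "2D")
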