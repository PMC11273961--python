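"""Detector construction contracts, inference behaviour, checkpoints."""

import numpy as np
import pytest

from murimetry import nn
from murimetry.errors import ConfigError
from murimetry.model import (Detector, ModelConfig, MouseDetection,
                             box_iou, build_model, decode_heatmaps,
                             decode_keypoints_structured, load_checkpoint,
                             nms, predict, save_checkpoint)


@pytest.fixture(scope="module")
def tiny_detector():
    return build_model(ModelConfig(seed=5))


class TestBuildModel:
    def test_keypoint_head_block_count(self):
        det = build_model(ModelConfig(keypoint_head_blocks=8))
        assert det.kp_head.n_blocks == 8
        convs = [l for l in det.kp_head.net.layers
                 if isinstance(l, nn.Conv2d)]
        bns = [l for l in det.kp_head.net.layers
               if isinstance(l, nn.BatchNorm2d)]
        deconvs = [l for l in det.kp_head.net.layers
                   if isinstance(l, nn.ConvTranspose2d)]
        assert len(convs) == 8 and len(bns) == 8 and len(deconvs) == 1
        assert det.kp_head.net.layers[-1] is det.kp_head.deconv

    @pytest.mark.parametrize("blocks", [1, 4])
    def test_block_count_configurable(self, blocks):
        det = build_model(ModelConfig(keypoint_head_blocks=blocks))
        assert sum(isinstance(l, nn.Conv2d)
                   for l in det.kp_head.net.layers) == blocks

    def test_tiny_parameter_count_under_cap(self, tiny_detector):
        total = sum(v.size for v in tiny_detector.all_params().values())
        assert total < 1_000_000

    def test_same_seed_gives_identical_parameters(self):
        a = build_model(ModelConfig(seed=3))
        b = build_model(ModelConfig(seed=3))
        for key, val in a.all_params().items():
            assert np.array_equal(val, b.all_params()[key]), key

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError, match="backbone"):
            build_model(ModelConfig(backbone="resnet50"))

    def test_full_scale_backbone_constructs(self):
        det = build_model(ModelConfig(backbone="efficientnet_b3_fpn"))
        total = sum(v.size for v in det.all_params().values())
        assert total > 1_000_000  # B3-scale depth/width

    def test_parameter_groups_partition_all_parameters(self, tiny_detector):
        groups = tiny_detector.param_groups()
        assert set(groups) == {"backbone", "roi_header", "keypoint_header"}
        names = [set(g) for g in groups.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not names[i] & names[j]
        assert set(tiny_detector.all_params()) == set().union(*names)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_keypoints=10).validate()
        with pytest.raises(ConfigError):
            ModelConfig(keypoint_head_blocks=0).validate()
        with pytest.raises(ConfigError):
            ModelConfig(score_threshold=1.5).validate()


class TestPredict:
    def test_empty_image_list(self, tiny_detector):
        assert predict(tiny_detector, []) == []

    def test_non_2d_raster_rejected(self, tiny_detector):
        with pytest.raises(ConfigError):
            predict(tiny_detector, [np.zeros((8, 8, 3), dtype=np.float32)])

    def test_eval_mode_is_deterministic(self, tiny_detector, two_mouse_scene):
        a = predict(tiny_detector, [two_mouse_scene.image])[0]
        b = predict(tiny_detector, [two_mouse_scene.image])[0]
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert np.array_equal(da.keypoints.coords, db.keypoints.coords)
            assert da.top_view_prob == db.top_view_prob

    def test_detections_sorted_and_contain_keypoints(self, tiny_detector,
                                                     two_mouse_scene):
        dets = predict(tiny_detector, [two_mouse_scene.image])[0]
        probs = [d.top_view_prob for d in dets]
        assert probs == sorted(probs, reverse=True)
        h, w = two_mouse_scene.image.shape
        for d in dets:
            kp = d.keypoints.coords
            assert np.all(kp[:, 0] >= d.box[0]) and np.all(kp[:, 0] <= d.box[2])
            assert np.all(kp[:, 1] >= d.box[1]) and np.all(kp[:, 1] <= d.box[3])
            assert d.keypoints.scores is not None


class TestDecoding:
    def _logits_with_peaks(self, peaks, size=32):
        logits = np.zeros((12, size, size), dtype=np.float32)
        ys, xs = np.mgrid[0:size, 0:size]
        for k, (px, py) in enumerate(peaks):
            logits[k] = 8.0 * np.exp(-((xs - px) ** 2 + (ys - py) ** 2) / 4.0)
        return logits

    def test_exact_peak_recovered(self):
        peaks = [(5 + k, 7 + (k % 3)) for k in range(12)]
        logits = self._logits_with_peaks(peaks)
        coords, scores = decode_heatmaps(logits, 100, 200)
        for k, (px, py) in enumerate(peaks):
            assert coords[k, 0] == pytest.approx(100 + px, abs=0.05)
            assert coords[k, 1] == pytest.approx(200 + py, abs=0.05)
        assert np.all(scores > 0) and np.all(scores <= 1)

    def test_structured_decode_separates_collapsed_mirror_pair(self):
        from murimetry.io import keypoint_index

        peaks = [(5 + 2 * k, 25) for k in range(12)]
        kl = keypoint_index("tibia", "L", "end")
        kr = keypoint_index("tibia", "R", "end")
        peaks[kl] = (10, 10)
        peaks[kr] = (10, 10)  # collapsed onto the left peak
        logits = self._logits_with_peaks(peaks)
        # give the right-side map a secondary peak at its true location
        ys, xs = np.mgrid[0:32, 0:32]
        logits[kr] += 6.0 * np.exp(-((xs - 24) ** 2 + (ys - 10) ** 2) / 4.0)
        logits[kl] += 0.5  # left is the stronger claimant
        coords, _ = decode_keypoints_structured(logits, 0, 0)
        assert np.hypot(*(coords[kl] - (10, 10))) < 1.0
        assert np.hypot(*(coords[kr] - (24, 10))) < 1.0


class TestFlipMerge:
    def test_merge_views_inverts_each_transform_exactly(self, rng):
        """Constructing each view by the forward transform and merging must
        reproduce the original logits (the merge is the exact inverse)."""
        from murimetry.io import LR_SWAP
        from murimetry.model import _merge_views

        swap = np.asarray(LR_SWAP)
        base = rng.normal(size=(36, 16, 16)).astype(np.float32)
        hm, off = base[:12], base[12:].reshape(12, 2, 16, 16)
        views, flips = [], []
        for fx, fy in ((False, False), (True, False), (False, True),
                       (True, True)):
            h2, o2 = hm.copy(), off.copy()
            if fx:
                h2 = h2[:, :, ::-1]
                o2 = np.stack([-o2[:, 0, :, ::-1], o2[:, 1, :, ::-1]], axis=1)
            if fy:
                h2 = h2[:, ::-1, :]
                o2 = np.stack([o2[:, 0, ::-1, :], -o2[:, 1, ::-1, :]], axis=1)
            if fx != fy:
                h2 = h2[swap]
                o2 = o2[swap]
            views.append(np.concatenate([h2, o2.reshape(24, 16, 16)]))
            flips.append((fx, fy))
        merged = _merge_views(views, flips, 12)
        assert np.allclose(merged, base, atol=1e-6)


class TestBoxUtils:
    def test_iou_known_value(self):
        a = np.array([[0, 0, 10, 10]])
        b = np.array([[5, 5, 15, 15]])
        assert box_iou(a, b)[0, 0] == pytest.approx(25 / 175)

    def test_nms_suppresses_overlaps(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]])
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.3)
        assert keep == [0, 2]


class TestCheckpoint:
    def test_round_trip_preserves_everything(self, tmp_path, tiny_detector,
                                             two_mouse_scene):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_detector, path)
        back = load_checkpoint(path)
        assert back.config == tiny_detector.config
        for key, val in tiny_detector.all_params().items():
            assert np.array_equal(val, back.all_params()[key]), key
        for key, val in tiny_detector.buffers().items():
            assert np.array_equal(val, back.buffers()[key]), key
        a = predict(tiny_detector, [two_mouse_scene.image])[0]
        b = predict(back, [two_mouse_scene.image])[0]
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert np.array_equal(da.keypoints.coords, db.keypoints.coords)


class TestMouseDetection:
    def test_probability_bounds_enforced(self):
        from murimetry.io import KeypointSet

        with pytest.raises(ConfigError):
            MouseDetection(np.zeros(4), 1.5, KeypointSet(np.zeros((12, 2))))
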