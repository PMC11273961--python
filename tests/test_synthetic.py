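"""Synthetic radiograph generator: geometry, determinism, dataset layout."""

import numpy as np
import pytest

from murimetry.errors import ConfigError, MurimetryError
from murimetry.io import BONES, SIDES, read_coco_keypoints
from murimetry.synthetic import (SceneConfig, generate_cohort,
                                 generate_dataset, generate_scene,
                                 growth_curve, split_sizes)


class TestGenerateScene:
    def test_empty_scene_is_pure_noise(self):
        scene = generate_scene(SceneConfig(n_mice=0, seed=1))
        assert scene.mice == []
        assert scene.image.shape == (256, 256)
        # background: no bright bone pixels anywhere
        assert scene.image.max() < 0.5

    def test_fixed_seed_is_bit_identical(self):
        a = generate_scene(SceneConfig(n_mice=2, seed=7))
        b = generate_scene(SceneConfig(n_mice=2, seed=7))
        assert np.array_equal(a.image, b.image)
        for ma, mb in zip(a.mice, b.mice):
            assert np.array_equal(ma.keypoints.coords, mb.keypoints.coords)
            assert np.array_equal(ma.box, mb.box)

    @pytest.mark.parametrize("integer_kp", [True, False])
    @pytest.mark.parametrize("seed", [0, 11, 42])
    def test_stored_lengths_equal_endpoint_distances(self, seed, integer_kp):
        scene = generate_scene(SceneConfig(n_mice=2, seed=seed,
                                           integer_keypoints=integer_kp))
        for mouse in scene.mice:
            for bone in BONES:
                for side in SIDES:
                    p0, p1, v0, v1 = mouse.keypoints.endpoint_pair(bone, side)
                    assert v0 and v1
                    dist = np.linalg.norm(p1 - p0)
                    assert dist == pytest.approx(mouse.lengths[(bone, side)],
                                                 abs=1e-9)

    def test_integer_keypoints_snap_to_grid(self):
        scene = generate_scene(SceneConfig(n_mice=1, seed=5,
                                           integer_keypoints=True))
        coords = scene.mice[0].keypoints.coords
        assert np.allclose(coords, np.round(coords))

    def test_keypoints_inside_box_and_boxes_disjoint(self):
        scene = generate_scene(SceneConfig(n_mice=2, seed=9))
        boxes = [m.box for m in scene.mice]
        for mouse in scene.mice:
            kp = mouse.keypoints.coords
            x0, y0, x1, y1 = mouse.box
            assert np.all(kp[:, 0] >= x0) and np.all(kp[:, 0] < x1)
            assert np.all(kp[:, 1] >= y0) and np.all(kp[:, 1] < y1)
        a, b = boxes
        no_overlap = (a[2] <= b[0] or b[2] <= a[0]
                      or a[3] <= b[1] or b[3] <= a[1])
        assert no_overlap

    def test_anatomical_adjacency(self):
        cfg = SceneConfig(n_mice=1, seed=13)
        scene = generate_scene(cfg)
        ks = scene.mice[0].keypoints
        tol = cfg.adjacency_jitter + 1.5  # articulation jitter + rounding
        for side in SIDES:
            for child, parent in (("femur", "pelvis"), ("tibia", "femur")):
                c0, _, _, _ = ks.endpoint_pair(child, side)
                _, p1, _, _ = ks.endpoint_pair(parent, side)
                assert np.linalg.norm(c0 - p1) <= tol

    def test_unplaceable_config_rejected(self):
        cfg = SceneConfig(n_mice=2, image_width=128, image_height=128,
                          max_place_attempts=10)
        with pytest.raises(MurimetryError):
            generate_scene(cfg)

    @pytest.mark.parametrize("bad", [
        dict(n_mice=3), dict(image_width=32), dict(length_sd=-1.0),
        dict(bone_thickness=20.0)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            generate_scene(SceneConfig(**bad))


class TestGenerateDataset:
    def test_table_one_split_sizes(self):
        assert split_sizes(94, (64 / 94, 11 / 94, 19 / 94)) == [64, 11, 19]

    def test_minimal_equal_split(self):
        assert split_sizes(3, (1 / 3, 1 / 3, 1 / 3)) == [1, 1, 1]

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            split_sizes(10, (0.5, 0.2, 0.2))

    def test_dataset_layout_and_determinism(self, tmp_path):
        cfg = SceneConfig(seed=21)
        m1 = generate_dataset(8, (0.5, 0.25, 0.25), cfg, tmp_path / "a")
        m2 = generate_dataset(8, (0.5, 0.25, 0.25), cfg, tmp_path / "b")
        assert m1.equals(m2)
        assert list(m1["split"].value_counts()[["train", "val", "test"]]) \
            == [4, 2, 2]
        # mouse-count conservation: manifest total equals annotation total
        total = 0
        for split in ("train", "val", "test"):
            recs = read_coco_keypoints(tmp_path / "a" / split /
                                       "annotations.json")
            total += sum(len(r.mice) for r in recs)
        assert total == int(m1["n_mice"].sum())

    def test_round_trip_reproduces_ground_truth(self, tmp_path):
        cfg = SceneConfig(seed=33)
        generate_dataset(4, (0.5, 0.25, 0.25), cfg,
                         tmp_path, mice_counts=[2, 1, 2, 1])
        recs = read_coco_keypoints(tmp_path / "train" / "annotations.json")
        assert sum(len(r.mice) for r in recs) == 3
        for rec in recs:
            for mouse in rec.mice:
                assert mouse.keypoints.coords.shape == (12, 2)
                assert np.allclose(mouse.keypoints.coords,
                                   np.round(mouse.keypoints.coords))


class TestCohortSimulation:
    def test_growth_curve_monotone_and_sexed(self):
        ages = np.linspace(20, 200, 50)
        male = growth_curve(ages, np.array(["M"] * 50), "tibia")
        female = growth_curve(ages, np.array(["F"] * 50), "tibia")
        assert np.all(np.diff(male) > 0)
        assert np.all(male > female)

    def test_cohort_frame_shape_and_noise(self):
        df = generate_cohort(400, seed=4, noise_sd=0.3)
        assert len(df) == 400
        assert set(df["sex"]) == {"M", "F"}
        resid = df["tibia_L"] - growth_curve(df["age"], df["sex"], "tibia")
        assert np.std(resid) == pytest.approx(0.3, rel=0.15)
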