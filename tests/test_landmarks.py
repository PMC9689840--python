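"""Landmark schemas, heatmap decoding and training plumbing."""

import numpy as np
import pytest

from limbalign.landmarks import (LandmarkSet, Point, SchemaError,
                                 decode_heatmaps, landmark_schema,
                                 make_landmark_set, train_landmark_model)
from limbalign.models import (LandmarkTrainConfig, augment_crop,
                              render_heatmaps)


class TestSchemas:
    def test_counts(self):
        assert len(landmark_schema("proximal_femur")) == 9
        assert len(landmark_schema("knee_native")) == 20
        assert len(landmark_schema("knee_tka")) == 15
        assert len(landmark_schema("talus")) == 2

    def test_proximal_femur_head_contour_roles(self):
        roles = [e.role for e in landmark_schema("proximal_femur")]
        assert roles.count("head_contour") == 5

    def test_tka_component_split(self):
        schema = landmark_schema("knee_tka")
        assert sum(1 for e in schema if e.component == "femoral") == 5
        assert sum(1 for e in schema if e.component == "tibial") == 10

    def test_knee_native_component_split(self):
        schema = landmark_schema("knee_native")
        assert sum(1 for e in schema if e.component == "femoral") == 10
        assert sum(1 for e in schema if e.component == "tibial") == 10

    def test_unknown_region(self):
        with pytest.raises(SchemaError):
            landmark_schema("patella")

    def test_wrong_point_count_rejected(self):
        with pytest.raises(SchemaError):
            make_landmark_set("talus", np.zeros((3, 2)))


class TestDecodeHeatmaps:
    def test_delta_peak(self):
        hm = np.zeros((2, 64, 64))
        hm[0, 20, 10] = 1.0   # (x=10, y=20)
        hm[1, 40, 30] = 1.0
        ls = decode_heatmaps(hm, "talus", peak_threshold=0.2)
        p = ls.points[0]
        assert (p.x, p.y) == (10.0, 20.0)
        assert p.confidence == 1.0

    def test_gaussian_subpixel_vs_full_com_oracle(self):
        g = np.arange(64, dtype=float)
        cx, cy = 30.5, 40.5
        hm = np.exp(-(((g - cy)[:, None] ** 2) + ((g - cx)[None, :] ** 2)) / 2.0)
        full_cx = (hm.sum(axis=0) * g).sum() / hm.sum()
        full_cy = (hm.sum(axis=1) * g).sum() / hm.sum()
        stack = np.stack([hm, np.roll(hm, 5, axis=0)])
        ls = decode_heatmaps(stack, "talus")
        p = ls.points[0]
        assert abs(p.x - full_cx) <= 0.25
        assert abs(p.y - full_cy) <= 0.25

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        g = np.arange(96, dtype=float)
        hm = np.exp(-(((g - 40.0)[:, None] ** 2) + ((g - 30.0)[None, :] ** 2)) / 8.0)
        base = decode_heatmaps(np.stack([hm, hm]), "talus").points[0]
        shifted = np.roll(np.roll(hm, 7, axis=0), 11, axis=1)
        moved = decode_heatmaps(np.stack([shifted, shifted]), "talus").points[0]
        assert moved.x - base.x == pytest.approx(11.0, abs=1e-9)
        assert moved.y - base.y == pytest.approx(7.0, abs=1e-9)

    def test_all_zero_channel_marked_missing(self):
        hm = np.zeros((2, 32, 32))
        hm[0, 5, 5] = 1.0
        ls = decode_heatmaps(hm, "talus", peak_threshold=0.2)
        assert not ls.points[0].missing
        assert ls.points[1].missing
        assert ls.points[1].confidence == 0.0

    def test_channel_count_mismatch(self):
        with pytest.raises(SchemaError):
            decode_heatmaps(np.zeros((3, 16, 16)), "talus")


class TestAugmentation:
    def test_rotation_cotransforms_landmarks(self):
        """Rotating crop + landmarks, rendering targets and decoding gives
        back the rotated coordinates to subpixel accuracy."""
        rng = np.random.default_rng(3)
        pixels = rng.random((256, 256)).astype(np.float32)
        xy = np.array([[80.0, 120.0], [170.0, 60.0]])
        _, axy = augment_crop(pixels, xy, angle_deg=10.0, scale=1.0)
        hm = render_heatmaps(axy, 256, sigma=2.0)
        ls = decode_heatmaps(hm, "talus")
        np.testing.assert_allclose(ls.coords(), axy, atol=0.5)

    def test_identity_augment_is_noop_on_coords(self):
        xy = np.array([[10.0, 20.0], [200.0, 100.0]])
        pix = np.zeros((256, 256), np.float32)
        _, axy = augment_crop(pix, xy, angle_deg=0.0, scale=1.0)
        np.testing.assert_allclose(axy, xy, atol=1e-9)


def _tiny_crop_set(n, seed=0):
    rng = np.random.default_rng(seed)
    crops, lsets = [], []
    for _ in range(n):
        img = rng.random((256, 256)).astype(np.float32)
        xy = rng.uniform(60, 200, size=(2, 2))
        crops.append(img)
        lsets.append(make_landmark_set("talus", xy, frame="crop"))
    return crops, lsets


class TestLandmarkTables:
    def test_csv_round_trip_supports_geometry_only_path(self, tmp_path,
                                                        varus_phantom):
        """A saved landmark table re-loads into sets that reproduce the
        same angles through the goniometry alone."""
        from limbalign.geometry import build_axes, compute_alignment
        from limbalign.landmarks import load_landmarks_csv, save_landmarks_csv

        _, gt = varus_phantom
        path = tmp_path / "landmarks.csv"
        save_landmarks_csv(path, "img0", gt.landmarks)
        sets = load_landmarks_csv(path, "img0")
        assert set(sets) == set(gt.landmarks)
        rep = compute_alignment(build_axes(sets, gt.side,
                                           femur_mask=gt.shapes["femur"]))
        for k, v in rep.available().items():
            assert v == pytest.approx(gt.true_angles[k], abs=1e-6)

    def test_partial_table_yields_missing_points(self, tmp_path, varus_phantom):
        import pandas as pd

        from limbalign.landmarks import load_landmarks_csv, save_landmarks_csv

        _, gt = varus_phantom
        path = tmp_path / "landmarks.csv"
        save_landmarks_csv(path, "img0", gt.landmarks)
        df = pd.read_csv(path)
        df = df[df["name"] != "talus_dome_medial"]
        df.to_csv(path, index=False)
        sets = load_landmarks_csv(path)
        assert sets["talus"].get("talus_dome_medial").missing


class TestTraining:
    def test_deterministic_final_loss(self):
        crops, lsets = _tiny_crop_set(4)
        cfg = LandmarkTrainConfig(epochs=2, seed=5, internal_size=32, hidden=4)
        m1 = train_landmark_model("talus", crops, lsets, cfg)
        m2 = train_landmark_model("talus", crops, lsets, cfg)
        assert m1.history["loss_per_epoch"] == m2.history["loss_per_epoch"]

    def test_schema_mismatch_rejected(self):
        crops, lsets = _tiny_crop_set(2)
        with pytest.raises(SchemaError):
            train_landmark_model("proximal_femur", crops, lsets)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_landmark_model("talus", [], [])

    def test_checkpoint_round_trip(self, tmp_path):
        from limbalign.models import load_checkpoint

        crops, lsets = _tiny_crop_set(2)
        cfg = LandmarkTrainConfig(epochs=1, seed=1, internal_size=32, hidden=4)
        m = train_landmark_model("talus", crops, lsets, cfg)
        path = tmp_path / "talus.npz"
        m.save(path)
        m2 = load_checkpoint(path)
        np.testing.assert_array_equal(m.net.get_weights()[0],
                                      m2.net.get_weights()[0])
        p1 = m.predict(crops[0]).coords()
        p2 = m2.predict(crops[0]).coords()
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_training_error_not_worse_with_more_data(self):
        """Held-out talus landmark error does not degrade when the training
        set doubles (20 -> 40 crops), averaged over seeds."""
        from limbalign.evaluate import TinyPipeline, heldout_landmark_error
        from limbalign.training import phantom_crop_dataset

        crops40, lsets40 = phantom_crop_dataset("talus", 40, seed=500)
        means = {20: [], 40: []}
        for seed in (0, 1, 2):
            for n in (20, 40):
                cfg = LandmarkTrainConfig(epochs=8, seed=seed,
                                          internal_size=64, hidden=8)
                m = train_landmark_model("talus", crops40[:n], lsets40[:n], cfg)
                pipe = TinyPipeline(segmenter=None,
                                    landmark_models={"talus": m})
                err = heldout_landmark_error(pipe, "talus", n=5, seed=606)
                means[n].append(err["mean_error_px"])
        assert np.mean(means[40]) <= np.mean(means[20]) + 1.0
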