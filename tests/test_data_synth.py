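"""Annotation I/O, augmentation/tiling geometry, dual-dataset batching, and
the synthetic scene generator's self-consistency."""

import numpy as np
import pytest
from scipy import stats

from oriface.angles import angle_from_keypoints, transform_angle, angle_distance
from oriface.data import (
    AnnotatedImage,
    AugmentationConfig,
    DualBatcher,
    FaceRecord,
    OpProbabilities,
    augment,
    letterbox,
    read_annotations,
    tile,
    write_annotations,
)
from oriface.synth import SyntheticSceneSpec, generate_dataset, generate_scene


class TestAnnotationIO:
    def test_round_trip(self, tmp_path, sample_scenes):
        path = tmp_path / "ann.jsonl"
        write_annotations(path, sample_scenes, image_dir=tmp_path / "imgs")
        loaded = read_annotations(path, image_dir=tmp_path / "imgs")
        assert len(loaded) == len(sample_scenes)
        for a, b in zip(sample_scenes, loaded):
            assert a.dataset_tag == b.dataset_tag
            assert len(a.records) == len(b.records)
            for ra, rb in zip(a.records, b.records):
                np.testing.assert_allclose(ra.box, rb.box)
                assert ra.theta == pytest.approx(rb.theta)
                np.testing.assert_allclose(ra.keypoints, rb.keypoints)
            # PNG round trip quantizes to 8 bits
            np.testing.assert_allclose(a.image, b.image, atol=1 / 255 + 1e-6)

    def test_ds1_record_requires_angle(self):
        with pytest.raises(ValueError, match="lacks both angle and keypoints"):
            AnnotatedImage(
                image=np.zeros((10, 10, 1)),
                records=[FaceRecord(box=np.array([1, 1, 5, 5]))],
                dataset_tag="ds1",
            )

    def test_keypoints_produce_angle_on_load(self, tmp_path):
        from oriface.angles import KeypointPair

        ann = AnnotatedImage(
            image=np.zeros((20, 20, 1)),
            records=[
                FaceRecord(
                    box=np.array([2, 2, 18, 18]),
                    keypoints=KeypointPair(5.0, 14.0, 5.0, 7.0),  # vertical pair
                )
            ],
            dataset_tag="ds1",
        )
        assert ann.records[0].theta == pytest.approx(0.5)
        path = tmp_path / "a.jsonl"
        write_annotations(path, [ann], image_dir=tmp_path)
        assert read_annotations(path, tmp_path)[0].records[0].theta == pytest.approx(0.5)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"image": null, "width": 5, "height": 5, "channels": 1, '
                        '"dataset": "ds1", "objects": [{"box": [3, 3, 1, 1]}]}\n')
        with pytest.raises(ValueError, match="bad.jsonl:1"):
            read_annotations(path)


class TestAugment:
    def test_hflip_box_map(self):
        ann = AnnotatedImage(
            image=np.zeros((100, 100, 1)),
            records=[FaceRecord(box=np.array([10.0, 20.0, 30.0, 40.0]), theta=0.0)],
        )
        out = augment(ann, "hflip")
        np.testing.assert_allclose(out.records[0].box, [70.0, 20.0, 90.0, 40.0])

    def test_rot90_twice_plus_both_flips_is_identity(self, sample_scenes):
        ann = sample_scenes[0]
        out = ann
        for op in ("rot90ccw", "rot90ccw", "vflip", "hflip"):
            out = augment(out, op)
        np.testing.assert_array_equal(out.image, ann.image)
        for ra, rb in zip(ann.records, out.records):
            np.testing.assert_allclose(ra.box, rb.box, atol=1e-9)
            assert angle_distance(ra.theta, rb.theta) < 1e-9

    @pytest.mark.parametrize("op", ["rot90ccw", "hflip", "vflip"])
    def test_angle_delegation(self, sample_scenes, op):
        for ann in sample_scenes:
            out = augment(ann, op)
            for ra, rb in zip(ann.records, out.records):
                assert rb.theta == pytest.approx(transform_angle(ra.theta, op))

    @pytest.mark.parametrize("op", ["rot90ccw", "hflip", "vflip"])
    def test_pixels_follow_boxes(self, small_scene_spec, op):
        """The augmented glyph's pixel mass stays inside its transformed box."""
        ann = generate_scene(small_scene_spec, rng=5)
        out = augment(ann, op)
        fg = out.image[..., 0] > 0.5
        ys, xs = np.nonzero(fg)
        x0, y0, x1, y1 = np.concatenate(
            [np.min([r.box[:2] for r in out.records], axis=0),
             np.max([r.box[2:] for r in out.records], axis=0)]
        )
        assert xs.min() >= x0 - 1 and xs.max() <= x1 + 1
        assert ys.min() >= y0 - 1 and ys.max() <= y1 + 1


class TestTile:
    def test_2x2_scales_and_offsets(self, sample_scenes):
        ann = sample_scenes[0]
        out = tile([ann] * 4, "2x2")
        assert len(out.records) == 4 * len(ann.records)
        h, w, _ = ann.shape
        # record in tile 0 keeps its geometry at half scale
        for r_src, r_dst in zip(ann.records, out.records):
            np.testing.assert_allclose(r_dst.box, r_src.box * 0.5, atol=1e-9)
            assert r_dst.theta == r_src.theta  # isotropic scale: angle unchanged
        # same record in tile 3 is offset by (w/2, h/2)
        last = out.records[-len(ann.records):]
        for r_src, r_dst in zip(ann.records, last):
            np.testing.assert_allclose(
                r_dst.box, r_src.box * 0.5 + np.array([w // 2, h // 2, w // 2, h // 2]),
                atol=1e-9,
            )

    def test_record_count_and_angles_preserved(self, sample_scenes):
        group = sample_scenes[:9]
        out = tile(group, "3x3")
        assert len(out.records) == sum(len(a.records) for a in group)
        src_thetas = [r.theta for a in group for r in a.records]
        assert [r.theta for r in out.records] == src_thetas

    def test_wrong_count_rejected(self, sample_scenes):
        with pytest.raises(ValueError, match="needs 4"):
            tile(sample_scenes[:3], "2x2")


class TestLetterbox:
    def test_square_passthrough(self, sample_scenes):
        ann = sample_scenes[0]
        out = letterbox(ann, ann.shape[0])
        assert out is ann

    def test_scales_boxes_isotropically(self):
        ann = AnnotatedImage(
            image=np.ones((50, 100, 1)),
            records=[FaceRecord(box=np.array([10.0, 10.0, 30.0, 30.0]), theta=0.25)],
        )
        out = letterbox(ann, 200)
        assert out.shape == (200, 200, 1)
        np.testing.assert_allclose(out.records[0].box, [20, 20, 60, 60])
        assert out.records[0].theta == 0.25
        assert out.image[150:, :, 0].max() == 0.0  # bottom padding


class TestSynth:
    def test_theta_zero_glyph_geometry(self, small_scene_spec):
        from dataclasses import replace

        spec = replace(small_scene_spec, noise_std=0.0)
        for seed in range(30):
            ann = generate_scene(spec, rng=seed)
            for rec in ann.records:
                kp = rec.keypoints
                if abs(rec.theta) < 1e-6:
                    assert kp.xl < kp.xr and kp.yl == pytest.approx(kp.yr)

    def test_generator_self_consistency(self, small_scene_spec):
        """The angle recomputed from the rendered eye keypoints equals the
        sampled ground-truth angle."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            ann = generate_scene(small_scene_spec, rng=rng)
            for rec in ann.records:
                assert angle_distance(
                    angle_from_keypoints(rec.keypoints), rec.theta
                ) < 1e-6

    def test_boxes_inside_canvas_and_cover_glyph(self, small_scene_spec):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ann = generate_scene(small_scene_spec, rng=rng)
            h, w, _ = ann.shape
            for rec in ann.records:
                x0, y0, x1, y1 = rec.box
                assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h

    def test_theta_distribution_uniform(self):
        """Sampled angles are uniform on (-1, 1] (KS test)."""
        spec = SyntheticSceneSpec(size=96, face_radius=(10.0, 14.0), faces_min=1, faces_max=1)
        thetas = [
            ann.records[0].theta for ann in generate_dataset(400, spec, seed=21)
        ]
        res = stats.kstest(thetas, stats.uniform(loc=-1.0, scale=2.0).cdf)
        assert res.pvalue > 0.01

    def test_reproducible(self, small_scene_spec):
        a = generate_dataset(5, small_scene_spec, seed=9)
        b = generate_dataset(5, small_scene_spec, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)

    def test_ds2_strips_angles(self, small_scene_spec):
        ann = generate_scene(small_scene_spec, rng=1, dataset_tag="ds2")
        assert all(r.theta is None and r.keypoints is None for r in ann.records)


class TestBatcher:
    def test_batch_composition(self, sample_scenes):
        cfg = AugmentationConfig(t1=7, t2=5)
        batcher = DualBatcher(sample_scenes, None, cfg, input_size=96, seed=0)
        batch = batcher.next_batch()
        assert len(batch) == 12
        assert [b.dataset_tag for b in batch] == ["ds1"] * 7 + ["ds2"] * 5

    def test_zero_probabilities_passthrough(self, sample_scenes):
        off = OpProbabilities(0.0, 0.0, 0.0, 0.0, 0.0)
        cfg = AugmentationConfig(ds1=off, ds2=off, t1=2, t2=1)
        batcher = DualBatcher(sample_scenes, None, cfg, input_size=96, seed=0)
        batch = batcher.next_batch()
        originals = {img.image.tobytes() for img in sample_scenes}
        for ann in batch:
            assert ann.image.tobytes() in originals

    def test_deterministic_given_seed(self, sample_scenes):
        cfg = AugmentationConfig(t1=3, t2=2)
        b1 = DualBatcher(sample_scenes, None, cfg, input_size=96, seed=4)
        b2 = DualBatcher(sample_scenes, None, cfg, input_size=96, seed=4)
        for _ in range(3):
            x, y = b1.next_batch(), b2.next_batch()
            for a, b in zip(x, y):
                np.testing.assert_array_equal(a.image, b.image)

    def test_stream_covers_all_images_each_epoch(self, sample_scenes):
        off = OpProbabilities(0.0, 0.0, 0.0, 0.0, 0.0)
        cfg = AugmentationConfig(ds1=off, ds2=off, t1=4, t2=0)
        batcher = DualBatcher(sample_scenes, None, cfg, input_size=96, seed=0)
        n = len(sample_scenes)
        seen = set()
        for _ in range(-(-n // 4)):  # ceil(N / T1) batches
            for ann in batcher.next_batch():
                seen.add(ann.image.tobytes())
        assert len(seen) == n

    def test_augmentation_consistency_through_batcher(self, sample_scenes):
        """Angles carried by batched records stay consistent with their
        keypoints, whatever ops fired."""
        cfg = AugmentationConfig(t1=4, t2=0)
        batcher = DualBatcher(sample_scenes, None, cfg, input_size=96, seed=8)
        for _ in range(5):
            for ann in batcher.next_batch():
                for rec in ann.records:
                    if rec.keypoints is not None:
                        assert angle_distance(
                            angle_from_keypoints(rec.keypoints), rec.theta
                        ) < 1e-6
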