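"""Post-processing (thresholding, NMS, angle assembly) and face normalization."""

import numpy as np
import pytest

from oriface.anchors import generate_anchors
from oriface.angles import angle_from_keypoints, angle_distance
from oriface.boxes import corners_to_center, encode_boxes, iou_matrix
from oriface.inference import Detection, nms, normalize_face, postprocess
from oriface.network import DecodedHead
from oriface.synth import SyntheticSceneSpec, generate_scene


def _decoded_for(anchors, objectness, encodings=None, ccw=None, value=None):
    n = len(anchors)
    return DecodedHead(
        objectness=np.asarray(objectness, dtype=np.float64),
        box_encodings=np.zeros((n, 4)) if encodings is None else np.asarray(encodings),
        ccw_prob=np.full(n, 0.5) if ccw is None else np.asarray(ccw),
        angle_value=np.full(n, 0.5) if value is None else np.asarray(value),
    )


def _brute_force_nms(corners, scores, thresh):
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    keep = []
    for i in order:
        ok = True
        for j in keep:
            if iou_matrix(corners[i : i + 1], corners[j : j + 1])[0, 0] >= thresh:
                ok = False
                break
        if ok:
            keep.append(int(i))
    return keep


class TestNMS:
    def test_duplicate_suppressed(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
        kept = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert list(kept) == [0]

    def test_disjoint_all_kept(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30.0]])
        kept = nms(boxes, np.array([0.5, 0.9]), 0.5)
        assert sorted(kept) == [0, 1]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 20))
            xy = rng.uniform(0, 80, size=(n, 2))
            wh = rng.uniform(5, 40, size=(n, 2))
            corners = np.column_stack([xy, xy + wh])
            scores = rng.uniform(0, 1, size=n).round(2)  # rounding makes ties likely
            thresh = float(rng.uniform(0.2, 0.8))
            np.testing.assert_array_equal(
                nms(corners, scores, thresh), _brute_force_nms(corners, scores, thresh)
            )


class TestPostprocess:
    @pytest.fixture()
    def anchors(self):
        return generate_anchors(64, 64, strides=(16,), base_sizes=(24.0,))

    def test_all_below_threshold_empty(self, anchors):
        d = _decoded_for(anchors, np.full(len(anchors), 0.2))
        assert postprocess(d, anchors, score_thresh=0.5) == []

    def test_angle_assembly_sign(self, anchors):
        obj = np.zeros(len(anchors))
        obj[0] = 0.9
        ccw = np.full(len(anchors), 0.2)
        value = np.full(len(anchors), 0.4)
        d = _decoded_for(anchors, obj, ccw=ccw, value=value)
        dets = postprocess(d, anchors, score_thresh=0.5)
        assert len(dets) == 1
        assert dets[0].theta == pytest.approx(-0.4)  # ccw prob 0.2 -> clockwise

    def test_boxes_decoded_against_anchors(self, anchors):
        gt_center = np.array([[30.0, 28.0, 20.0, 14.0]])
        enc = encode_boxes(np.repeat(gt_center, len(anchors), 0), anchors.centers)
        obj = np.zeros(len(anchors))
        obj[5] = 0.8
        d = _decoded_for(anchors, obj, encodings=enc)
        dets = postprocess(d, anchors, score_thresh=0.5)
        np.testing.assert_allclose(
            corners_to_center(dets[0].box)[None], gt_center, rtol=1e-6
        )

    def test_max_dets_cap(self, anchors):
        d = _decoded_for(anchors, np.full(len(anchors), 0.9))
        dets = postprocess(d, anchors, score_thresh=0.5, nms_iou=0.99, max_dets=3)
        assert len(dets) == 3


class TestNormalizeFace:
    def _eye_angle_in_chip(self, spec, theta, out_size=96):
        """Render one glyph at a known angle, normalize with the exact
        detection, and measure the eye angle inside the chip."""
        from dataclasses import replace

        spec = replace(spec, noise_std=0.0, faces_min=1, faces_max=1)
        rng = np.random.default_rng(0)
        for _ in range(200):
            ann = generate_scene(spec, rng=rng)
            if angle_distance(ann.records[0].theta, theta) < 0.08:
                break
        rec = ann.records[0]
        det = Detection(box=rec.box, score=1.0, theta=rec.theta)
        face = normalize_face(ann.image, det, out_size=out_size)
        chip = face.chip[..., 0]
        # eyes are the darkest blobs; find their centroids in the chip
        mask = chip < (spec.eye_intensity + spec.face_intensity) / 2
        mask &= chip > 0.0  # ignore zero padding
        ys, xs = np.nonzero(mask)
        assert len(xs) > 4, "eyes not visible in chip"
        left_sel = xs < np.median(xs)
        eye_l = (xs[left_sel].mean(), ys[left_sel].mean())
        eye_r = (xs[~left_sel].mean(), ys[~left_sel].mean())
        from oriface.angles import KeypointPair

        return angle_from_keypoints(KeypointPair(*eye_l, *eye_r)), ann, det

    def test_theta_zero_is_plain_crop(self, small_scene_spec):
        angle, ann, det = self._eye_angle_in_chip(small_scene_spec, 0.0)
        assert abs(angle) < 0.05

    @pytest.mark.parametrize("theta", [0.5, -0.5, 1.0, 0.25, -0.7])
    def test_chip_eye_line_is_horizontal(self, small_scene_spec, theta):
        """After normalization the recomputed eye angle is ~0: the rotation
        undoes the face's orientation and keeps the left eye on the left."""
        angle, _, _ = self._eye_angle_in_chip(small_scene_spec, theta)
        assert angle_distance(angle, 0.0) < 0.05

    def test_output_shape_and_padding(self, small_scene_spec):
        ann = generate_scene(small_scene_spec, rng=3)
        rec = ann.records[0]
        det = Detection(box=rec.box, score=1.0, theta=rec.theta)
        face = normalize_face(ann.image, det, out_size=48)
        assert face.chip.shape == (48, 48, 1)
        assert face.detection is det

    def test_degenerate_box_rejected(self, small_scene_spec):
        ann = generate_scene(small_scene_spec, rng=3)
        det = Detection(box=np.array([10.0, 10.0, 10.0, 20.0]), score=1.0, theta=0.0)
        with pytest.raises(ValueError):
            normalize_face(ann.image, det)

    def test_idempotence(self, small_scene_spec):
        """Normalizing an already-normalized chip changes little."""
        from dataclasses import replace

        spec = replace(small_scene_spec, noise_std=0.0)
        ann = generate_scene(spec, rng=9)
        rec = ann.records[0]
        det = Detection(box=rec.box, score=1.0, theta=rec.theta)
        chip1 = normalize_face(ann.image, det, out_size=64).chip
        det2 = Detection(box=np.array([0.0, 0.0, 64.0, 64.0]), score=1.0, theta=0.0)
        chip2 = normalize_face(chip1, det2, out_size=64).chip
        assert np.abs(chip1 - chip2).mean() < 0.02


class TestRotationEquivariance:
    def test_rot90_of_scene_gives_matching_chips(self, small_scene_spec):
        """Rotating the scene by 90 degrees and re-running detection-frame
        normalization yields (approximately) the same chips."""
        from dataclasses import replace
        from oriface.data import augment

        spec = replace(small_scene_spec, noise_std=0.0, faces_min=1, faces_max=1)
        ann = generate_scene(spec, rng=21)
        rot = augment(ann, "rot90ccw")
        chips = []
        for scene in (ann, rot):
            rec = scene.records[0]
            det = Detection(box=rec.box, score=1.0, theta=rec.theta)
            chips.append(normalize_face(scene.image, det, out_size=64).chip)
        assert np.abs(chips[0] - chips[1]).mean() < 0.05  # < 5% of intensity range
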