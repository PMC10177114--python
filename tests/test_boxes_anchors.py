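"""Box arithmetic, anchor generation, matching and mini-batch sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oriface.anchors import (
    IGNORED,
    NEGATIVE,
    POSITIVE,
    generate_anchors,
    match_anchors,
    sample_minibatch,
)
from oriface.boxes import (
    center_to_corners,
    corners_to_center,
    decode_boxes,
    encode_boxes,
    iou_matrix,
)


class TestAnchors:
    def test_default_anchor_count_at_400(self):
        """The default four-level grid at 400x400 carries exactly 20,058 anchors."""
        anchors = generate_anchors(400, 400)
        assert len(anchors) == 20_058
        assert anchors.grid_sizes == ((50, 50), (25, 25), (13, 13), (7, 7))

    def test_single_level_tiny_grid(self):
        anchors = generate_anchors(64, 64, strides=(32,), base_sizes=(32.0,),
                                   scale_ratios=(1.0,), aspect_ratios=(1.0,))
        assert len(anchors) == 4
        np.testing.assert_allclose(
            anchors.centers[:, :2], [[16, 16], [48, 16], [16, 48], [48, 48]]
        )

    @settings(max_examples=30, deadline=None)
    @given(
        w=st.integers(min_value=32, max_value=500),
        h=st.integers(min_value=32, max_value=500),
    )
    def test_anchor_count_closed_form(self, w, h):
        anchors = generate_anchors(w, h)
        expected = 6 * sum(-(-w // s) * (-(-h // s)) for s in anchors.strides)
        assert len(anchors) == expected

    def test_templates_constant_area_per_scale(self):
        anchors = generate_anchors(64, 64, strides=(32,), base_sizes=(32.0,))
        wh = anchors.centers[:6, 2:]
        areas = wh[:, 0] * wh[:, 1]
        np.testing.assert_allclose(areas[:3], 32.0**2, rtol=1e-12)
        np.testing.assert_allclose(areas[3:], 64.0**2, rtol=1e-12)
        aspects = wh[:, 0] / wh[:, 1]
        np.testing.assert_allclose(aspects, [1.0, 2.0, 0.5, 1.0, 2.0, 0.5], rtol=1e-12)

    def test_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            generate_anchors(0, 100)


class TestEncodeDecode:
    def test_identity(self):
        a = np.array([[100.0, 100.0, 50.0, 50.0]])
        np.testing.assert_allclose(encode_boxes(a, a), 0.0)
        np.testing.assert_allclose(decode_boxes(np.zeros((1, 4)), a), a)

    def test_hand_values(self):
        anchor = np.array([[100.0, 100.0, 50.0, 50.0]])
        gt = np.array([[105.0, 100.0, 50.0, 50.0]])
        np.testing.assert_allclose(encode_boxes(gt, anchor), [[1.0, 0, 0, 0]], atol=1e-12)
        np.testing.assert_allclose(decode_boxes([[1.0, 0, 0, 0]], anchor)[0, 0], 105.0)
        anchor2 = np.array([[0.0, 0.0, 10.0, 10.0]])
        gt2 = np.array([[0.0, 0.0, 10.0 * np.e, 10.0]])
        np.testing.assert_allclose(encode_boxes(gt2, anchor2)[0, 2], 5.0, rtol=1e-12)

    def test_round_trip_random(self, rng):
        anchors = np.column_stack(
            [rng.uniform(0, 400, 1000), rng.uniform(0, 400, 1000),
             rng.uniform(5, 200, 1000), rng.uniform(5, 200, 1000)]
        )
        gts = np.column_stack(
            [rng.uniform(0, 400, 1000), rng.uniform(0, 400, 1000),
             rng.uniform(5, 200, 1000), rng.uniform(5, 200, 1000)]
        )
        rt = decode_boxes(encode_boxes(gts, anchors), anchors)
        np.testing.assert_allclose(rt, gts, rtol=1e-6)
        corners = center_to_corners(gts)
        np.testing.assert_allclose(corners_to_center(corners), gts, rtol=1e-9)


class TestIoU:
    def test_cases(self):
        b = np.array([[0.0, 0.0, 2.0, 2.0]])
        assert iou_matrix(b, b)[0, 0] == 1.0
        assert iou_matrix(b, [[5.0, 5.0, 6.0, 6.0]])[0, 0] == 0.0
        assert iou_matrix(b, [[1.0, 0.0, 3.0, 2.0]])[0, 0] == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100), data=st.data())
    def test_symmetry_and_scale_invariance(self, scale, data):
        coords = data.draw(
            st.lists(st.floats(min_value=0, max_value=100), min_size=8, max_size=8)
        )
        a = np.array([sorted(coords[0:2])[0], sorted(coords[2:4])[0],
                      sorted(coords[0:2])[1] + 1, sorted(coords[2:4])[1] + 1])
        b = np.array([sorted(coords[4:6])[0], sorted(coords[6:8])[0],
                      sorted(coords[4:6])[1] + 1, sorted(coords[6:8])[1] + 1])
        ab = iou_matrix([a], [b])[0, 0]
        ba = iou_matrix([b], [a])[0, 0]
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0
        scaled = iou_matrix([a * scale], [b * scale])[0, 0]
        assert scaled == pytest.approx(ab, abs=1e-9)


def _brute_force_match(anchor_corners, gt_corners, pos_t, neg_t):
    n, g = len(anchor_corners), len(gt_corners)
    labels = np.full(n, NEGATIVE)
    gt_idx = np.full(n, -1)
    if g == 0:
        return labels, gt_idx
    ious = iou_matrix(anchor_corners, gt_corners)
    for i in range(n):
        best = int(np.argmax(ious[i]))
        if ious[i, best] >= pos_t:
            labels[i], gt_idx[i] = POSITIVE, best
        elif ious[i, best] >= neg_t:
            labels[i] = IGNORED
    for j in range(g):
        i = int(np.argmax(ious[:, j]))
        if ious[i, j] > 0:
            labels[i], gt_idx[i] = POSITIVE, j
    return labels, gt_idx


class TestMatching:
    def test_exact_anchor_is_positive(self):
        anchors = generate_anchors(64, 64, strides=(32,), base_sizes=(32.0,))
        gt = center_to_corners(anchors.centers[0:1])
        m = match_anchors(anchors, gt)
        assert m.labels[0] == POSITIVE
        assert m.gt_index[0] == 0

    def test_no_gt_all_negative(self):
        anchors = generate_anchors(64, 64, strides=(32,), base_sizes=(32.0,))
        m = match_anchors(anchors, np.zeros((0, 4)))
        assert (m.labels == NEGATIVE).all()

    def test_matches_brute_force_oracle(self, rng):
        anchors = generate_anchors(96, 96, strides=(48,), base_sizes=(40.0,))
        assert len(anchors) <= 50
        for _ in range(20):
            n_gt = int(rng.integers(0, 4))
            xy = rng.uniform(0, 60, size=(n_gt, 2))
            wh = rng.uniform(10, 40, size=(n_gt, 2))
            gts = np.column_stack([xy, xy + wh])
            m = match_anchors(anchors, gts, 0.5, 0.4)
            labels, gt_idx = _brute_force_match(anchors.corners, gts, 0.5, 0.4)
            np.testing.assert_array_equal(m.labels, labels)
            np.testing.assert_array_equal(m.gt_index, gt_idx)


class TestSampler:
    def _match(self, n_pos, n_neg):
        from oriface.anchors import MatchResult

        labels = np.array([POSITIVE] * n_pos + [NEGATIVE] * n_neg)
        gt = np.where(labels == POSITIVE, 0, -1)
        return MatchResult(labels, gt)

    def test_fill_rule(self):
        pos, neg = sample_minibatch(self._match(2, 100), size=8, pos_fraction=0.25, rng=0)
        assert len(pos) == 2 and len(neg) == 6

    def test_no_positives(self):
        pos, neg = sample_minibatch(self._match(0, 100), size=16, pos_fraction=0.5, rng=0)
        assert len(pos) == 0 and len(neg) == 16

    def test_caps_positives(self):
        pos, neg = sample_minibatch(self._match(50, 100), size=8, pos_fraction=0.25, rng=0)
        assert len(pos) == 2 and len(neg) == 6

    def test_deterministic_given_seed(self):
        m = self._match(30, 300)
        a = sample_minibatch(m, 64, 0.25, rng=42)
        b = sample_minibatch(m, 64, 0.25, rng=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
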