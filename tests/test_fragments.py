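"""Centroid tracking, fragment splitting and common-box cropping."""

import numpy as np
import pytest

import scleraflow as sf
from scleraflow.fragments import CentroidReport
from scleraflow.roi import GradientMap, ROIBox
from scleraflow.video import VideoSequence


def _gmap(arr):
    return GradientMap.from_array(np.asarray(arr, dtype=float))


def _center(x, y):
    return CentroidReport(x_c=x, y_c=y, n=1, p=1.0)


# -- weighted centroid ------------------------------------------------------


def test_single_pixel_centroid():
    g = np.zeros((10, 10))
    g[4, 7] = 0.9
    rep = sf.weighted_centroid(_gmap(g), ROIBox(0, 0, 10, 10), threshold=0.5)
    assert (rep.x_c, rep.y_c) == (7.0, 4.0)
    assert rep.n == 1


def test_equal_weights_symmetric_centroid():
    g = np.zeros((5, 12))
    g[2, 0] = g[2, 10] = 0.8
    rep = sf.weighted_centroid(_gmap(g), ROIBox(0, 0, 12, 5), threshold=0.5)
    assert np.isclose(rep.x_c, 5.0)


def test_weighted_mean_hand_oracle():
    """Weights 1.0 and 0.5 at columns 0 and 10: x_c = 10*0.5/1.5."""
    g = np.zeros((3, 12))
    g[0, 0], g[0, 10] = 1.0, 0.5
    rep = sf.weighted_centroid(_gmap(g), ROIBox(0, 0, 12, 3), threshold=0.25)
    assert np.isclose(rep.x_c, 10 * 0.5 / 1.5)
    assert np.isclose(rep.y_c, 0.0)


def test_literal_denominator_reading_differs():
    g = np.zeros((3, 12))
    g[0, 0], g[0, 10] = 1.0, 0.5
    rep = sf.weighted_centroid(
        _gmap(g), ROIBox(0, 0, 12, 3), threshold=0.25, literal_denominator=True
    )
    assert np.isclose(rep.x_c, 10 * 0.5 / 2)  # divides by n = 2 instead


def test_empty_support_raises():
    with pytest.raises(ValueError):
        sf.weighted_centroid(_gmap(np.zeros((4, 4))), ROIBox(0, 0, 4, 4), threshold=0.5)


# -- fragment splitting -----------------------------------------------------


def test_static_centers_single_fragment():
    centers = [_center(50.0, 40.0)] * 50
    frags = sf.split_fragments(centers, sf.FragmenterConfig())
    assert len(frags) == 1
    assert (frags[0].start_frame, frags[0].end_frame) == (0, 49)


def test_drift_beyond_limit_splits():
    """|160 - 50| = 110 > 100 forces a split between frames 1 and 2."""
    xs = (50.0, 52.0, 160.0, 162.0)
    centers = [_center(x, 0.0) for x in xs]
    frags = sf.split_fragments(centers, sf.FragmenterConfig(min_fragment_len=1))
    assert [(f.start_frame, f.end_frame) for f in frags] == [(0, 1), (2, 3)]


def test_no_roi_anywhere_yields_empty_list():
    assert sf.split_fragments([None] * 20, sf.FragmenterConfig()) == []


def test_fragments_disjoint_ordered_and_within_drift(rng):
    xs = np.cumsum(rng.normal(0, 30, size=120)) + 200
    centers = [None if i % 17 == 0 else _center(float(x), 0.0) for i, x in enumerate(xs)]
    frags = sf.split_fragments(centers, sf.FragmenterConfig(min_fragment_len=2))
    last_end = -1
    for f in frags:
        assert f.start_frame > last_end
        last_end = f.end_frame
        first = f.centers[0]
        for c in f.centers:
            assert np.hypot(c.x_c - first.x_c, c.y_c - first.y_c) <= 100.0


# -- common box and cropping ------------------------------------------------


def test_identical_rois_common_box():
    frag = sf.Fragment(0, 2, [_center(50, 40)] * 3)
    rois = [ROIBox(10, 20, 100, 80)] * 3
    frag = sf.common_box(frag, rois)
    assert frag.corner_min == (10.0, 20.0)
    assert frag.corner_max == (109.0, 99.0)
    assert frag.box_size == (100, 80)


def test_box_size_is_min_extent():
    frag = sf.Fragment(0, 2, [_center(60, 45)] * 3)
    rois = [ROIBox(0, 0, 100, 80), ROIBox(5, 2, 90, 70), ROIBox(1, 1, 95, 75)]
    frag = sf.common_box(frag, rois)
    assert frag.box_size == (90, 70)


def test_corner_points_bruteforce_oracle():
    rois = [ROIBox(0, 0, 100, 80), ROIBox(10, 5, 90, 70)]
    frag = sf.common_box(sf.Fragment(0, 1, [_center(50, 40)] * 2), rois)
    xs = [r.x0 for r in rois] + [r.x0 + r.width - 1 for r in rois]
    ys = [r.y0 for r in rois] + [r.y0 + r.height - 1 for r in rois]
    assert frag.corner_min == (min(xs), min(ys))
    assert frag.corner_max == (max(xs), max(ys))


def test_crop_identity_for_full_frame_roi(rng):
    frames = rng.random((3, 40, 50))
    video = VideoSequence(frames)
    frag = sf.Fragment(0, 2, [_center(24.5, 19.5)] * 3)
    frag = sf.common_box(frag, [ROIBox(0, 0, 50, 40)] * 3)
    out = sf.crop_fragment(video, frag)
    np.testing.assert_array_equal(out.frames, frames)


def test_single_frame_crop_shape(rng):
    video = VideoSequence(rng.random((1, 40, 50)))
    frag = sf.Fragment(0, 0, [_center(25.0, 20.0)])
    frag = sf.common_box(frag, [ROIBox(5, 5, 30, 20)])
    out = sf.crop_fragment(video, frag)
    assert out.frames.shape == (1, 20, 30)


def test_cropped_windows_stay_in_frame_near_border(rng):
    video = VideoSequence(rng.random((2, 40, 50)))
    frag = sf.Fragment(0, 1, [_center(1.0, 1.0), _center(48.0, 39.0)])
    frag = sf.common_box(frag, [ROIBox(0, 0, 30, 20)] * 2)
    out = sf.crop_fragment(video, frag)  # windows shifted inward, no padding
    assert out.frames.shape == (2, 20, 30)


def test_phantom_tube_present_in_every_crop(y_phantom):
    _, _, video, gt = y_phantom
    centers = []
    rois = []
    for t in range(len(video)):
        box, _ = sf.roi_from_frame(video[t], frame_index=t)
        g = sf.gradient_magnitude(video[t])
        thr = sf.knee_threshold(g)
        centers.append(sf.weighted_centroid(g, box, thr))
        rois.append(box)
    frags = sf.split_fragments(centers, sf.FragmenterConfig(min_fragment_len=2))
    assert len(frags) == 1
    frag = sf.common_box(frags[0], rois)
    out = sf.crop_fragment(video, frag)
    assert len({f.shape for f in out}) == 1
    # reproduce the crop windows on the ground-truth mask
    from scleraflow.fragments import _window_origin

    h_b, w_b = out.frame_shape
    for c in frag.centers:
        r0, c0 = _window_origin(c.rc, (w_b, h_b), video.frame_shape)
        assert gt.mask[r0 : r0 + h_b, c0 : c0 + w_b].sum() > 0
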