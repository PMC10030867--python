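"""Registration: ZNCC correlation, Shi-Tomasi + Lucas-Kanade, stabilization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import scleraflow as sf
from scleraflow.roi import ROIBox
from scleraflow.stabilize import ReferencePatch, zncc_direct
from scleraflow.video import VideoSequence


# -- reference patch --------------------------------------------------------


def test_reference_patch_is_half_roi(rng):
    video = VideoSequence(rng.random((2, 120, 140)))
    patch = sf.reference_patch(video, ROIBox(10, 20, 100, 80))
    assert patch.pixels.shape == (40, 50)  # 50% of each linear extent
    # centers coincide under floor rounding
    assert patch.center_rc == (20 + (80 - 1) / 2.0, 10 + (100 - 1) / 2.0)


def test_reference_patch_minimal_roi(rng):
    video = VideoSequence(rng.random((1, 20, 20)))
    patch = sf.reference_patch(video, ROIBox(4, 4, 4, 4))
    assert patch.pixels.shape == (2, 2)
    with pytest.raises(ValueError):
        sf.reference_patch(video, ROIBox(4, 4, 3, 3))


# -- correlation ------------------------------------------------------------


def test_self_match_recovers_shift_exactly(rng):
    frame = rng.random((40, 50))
    pix = frame[10:20, 12:22].copy()
    patch = ReferencePatch(pixels=pix, origin_rc=(5, 15))
    cmap, off = sf.correlate(frame, patch)
    assert (off.dy, off.dx) == (5.0, -3.0)
    assert np.isclose(cmap.G.max(), 1.0)


def test_negated_patch_anticorrelates(rng):
    frame = rng.random((30, 30))
    pix = 1.0 - frame[8:16, 4:12]
    patch = ReferencePatch(pixels=pix, origin_rc=(8, 4))
    cmap, _ = sf.correlate(frame, patch)
    assert np.isclose(cmap.G[8, 4], -1.0)


def test_small_map_matches_direct_double_sum():
    frame = np.array(
        [[1.0, 2.0, 0.0, 1.0], [3.0, 1.0, 2.0, 0.0], [0.0, 2.0, 1.0, 3.0], [1.0, 0.0, 3.0, 2.0]]
    )
    patch = np.array([[2.0, 0.0], [1.0, 2.0]])
    fast, _ = sf.correlate(frame, ReferencePatch(pixels=patch, origin_rc=(0, 0)))
    np.testing.assert_allclose(fast.G, zncc_direct(frame, patch), atol=1e-10)


def test_fast_correlation_equals_oracle_on_random_instances(rng):
    for _ in range(20):
        frame = rng.random((16, 16))
        patch = rng.random((5, 5))
        fast, _ = sf.correlate(frame, ReferencePatch(pixels=patch, origin_rc=(0, 0)))
        np.testing.assert_allclose(fast.G, zncc_direct(frame, patch), atol=1e-6)


def test_zero_variance_patch_rejected(rng):
    frame = rng.random((20, 20))
    with pytest.raises(ValueError):
        sf.correlate(frame, ReferencePatch(pixels=np.zeros((4, 4)), origin_rc=(0, 0)))


# -- keypoints --------------------------------------------------------------


def test_constant_frame_yields_no_keypoints():
    assert len(sf.detect_keypoints(np.full((64, 64), 0.3))) == 0


def test_detection_is_deterministic(y_phantom):
    _, _, video, _ = y_phantom
    a = sf.detect_keypoints(video[0])
    b = sf.detect_keypoints(video[0])
    np.testing.assert_array_equal(a, b)


def test_keypoint_near_phantom_junction(y_phantom):
    """The silhouette of a Y holds a corner at the branch node wedge.

    The wedge apex between the two children recedes from the centerline
    junction by about (w/2) / tan(half-angle); with the generator's minimum
    branching half-angle of 0.45 rad that bounds the corner-to-junction
    distance.
    """
    scene, _, video, gt = y_phantom
    from scleraflow.stabilize import _geometry_corners, _registration_frame

    pts = _geometry_corners(_registration_frame(video[0]))
    dx, dy = gt.offsets[0]
    jr, jc = scene.junctions[0]
    dists = np.hypot(pts[:, 0] - (jr + dy), pts[:, 1] - (jc + dx))
    bound = scene.segments[0].mean_width / 2 / np.tan(0.45) + 4.0
    assert dists.min() <= bound


# -- Lucas-Kanade tracking --------------------------------------------------


def test_identity_tracking_gives_zero_displacement(y_phantom):
    _, _, video, _ = y_phantom
    pts = sf.detect_keypoints(video[0])[:10]
    track = sf.track_keypoints(video[0], video[0], pts)
    assert track.status.all()
    assert np.abs(track.displacements).max() < 0.05


def test_known_translation_recovered_subpixel(y_phantom):
    _, _, video, _ = y_phantom
    f1 = video[0]
    f2 = np.roll(f1, (3, 0), axis=(0, 1))
    pts = sf.detect_keypoints(f1)
    pts = pts[(pts[:, 0] > 20) & (pts[:, 0] < f1.shape[0] - 20)]
    track = sf.track_keypoints(f1, f2, pts)
    d = track.displacements
    assert len(d) > 0
    assert np.abs(d - np.array([3.0, 0.0])).max() < 0.25


def test_textureless_point_flagged_lost(rng):
    f1 = np.zeros((60, 60))
    f1[10:20, 10:20] = rng.random((10, 10))  # structure far from the probe
    track = sf.track_keypoints(f1, f1, np.array([[45.0, 45.0]]))
    assert not track.status[0]


# -- matching rate ----------------------------------------------------------


@pytest.mark.parametrize(
    "kp1, kp2, m, expected",
    [(22, 22, 22, 100.0), (128, 119, 96, 77.7), (10, 30, 0, 0.0)],
)
def test_matching_rate_values(kp1, kp2, m, expected):
    assert round(sf.matching_rate(kp1, kp2, m), 1) == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    kp1=hst.integers(min_value=0, max_value=5000),
    kp2=hst.integers(min_value=1, max_value=5000),
    m=hst.integers(min_value=0, max_value=5000),
)
def test_matching_rate_symmetry(kp1, kp2, m):
    assert sf.matching_rate(kp1, kp2, m) == sf.matching_rate(kp2, kp1, m)


def test_matching_rate_undefined_for_no_points():
    with pytest.raises(ValueError):
        sf.matching_rate(0, 0, 0)


# -- frame offset -----------------------------------------------------------


def _track_from(disps):
    p1 = np.zeros((len(disps), 2))
    p2 = np.asarray(disps, dtype=float)
    return sf.KeypointTrack(points1=p1, points2=p2, status=np.ones(len(disps), bool))


def test_offset_unanimous():
    off = sf.frame_offset(_track_from([(0, 2), (0, 2), (0, 2)]))
    assert (off.dx, off.dy) == (2.0, 0.0)


def test_offset_median_resists_outlier():
    off = sf.frame_offset(_track_from([(0, 1), (0, 2), (0, 9)]))
    assert off.dx == 2.0


def test_offset_even_count_averages_middle():
    off = sf.frame_offset(_track_from([(1, 1), (3, 3)]))
    assert (off.dx, off.dy) == (2.0, 2.0)


def test_offset_requires_tracked_points():
    t = sf.KeypointTrack(
        points1=np.zeros((2, 2)), points2=np.zeros((2, 2)), status=np.zeros(2, bool)
    )
    with pytest.raises(ValueError):
        sf.frame_offset(t)


# -- stabilization ----------------------------------------------------------


def test_static_video_yields_zero_offsets(y_phantom):
    scene, speeds, _, _ = y_phantom
    video, _ = sf.render_video(scene, sf.MotionSpec(seed=4), np.zeros_like(speeds), 6)
    out, offsets = sf.stabilize(video, method="correlation")
    assert all(o.dx == 0 and o.dy == 0 for o in offsets)
    assert out.frames.shape == video.frames.shape


@pytest.mark.parametrize("method", ["correlation", "keypoint"])
def test_offsets_recovered_within_one_pixel(jittery_tree, method):
    _, _, video, gt = jittery_tree
    _, offsets = sf.stabilize(video, method=method)
    recovered = np.array([[o.dx, o.dy] for o in offsets])
    true = gt.offsets - gt.offsets[0]
    frac = (np.abs(recovered - true).max(axis=1) <= 1.0).mean()
    assert frac >= 0.95


def test_methods_agree_on_low_noise_phantom(jittery_tree):
    _, _, video, _ = jittery_tree
    sub = video.with_frames(video.frames[:20])
    _, off_c = sf.stabilize(sub, method="correlation")
    _, off_k = sf.stabilize(sub, method="keypoint")
    diffs = [
        max(abs(a.dx - b.dx), abs(a.dy - b.dy)) for a, b in zip(off_c, off_k)
    ]
    assert np.median(diffs) <= 1.0


def test_stabilization_idempotent(jittery_tree):
    _, _, video, _ = jittery_tree
    sub = video.with_frames(video.frames[:15])
    once, _ = sf.stabilize(sub, method="correlation")
    twice, offsets2 = sf.stabilize(once, method="correlation")
    assert max(max(abs(o.dx), abs(o.dy)) for o in offsets2) <= 1.0
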