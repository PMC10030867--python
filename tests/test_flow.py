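"""Photometric normalization, dense optical flow and velocimetry."""

import numpy as np
import pytest

import scleraflow as sf


# -- background normalization ----------------------------------------------


def test_background_flattened_vessels_untouched(y_phantom):
    _, _, video, gt = y_phantom
    frame = video[0]
    out = sf.normalize_background(frame, gt.mask, halo=5)
    outside = out[~gt.mask]
    assert np.allclose(outside, outside.flat[0])
    np.testing.assert_array_equal(out[gt.mask], frame[gt.mask])


def test_full_mask_is_identity(rng):
    frame = rng.random((20, 20))
    np.testing.assert_array_equal(
        sf.normalize_background(frame, np.ones((20, 20), bool)), frame
    )


def test_halo_mean_toy_oracle():
    frame = np.arange(25, dtype=float).reshape(5, 5) / 25.0
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    out = sf.normalize_background(frame, mask, halo=1)
    ring = [(1, 1), (1, 2), (1, 3), (2, 1), (2, 3), (3, 1), (3, 2), (3, 3)]
    expected = np.mean([frame[r, c] for r, c in ring])
    assert np.isclose(out[0, 0], expected)
    assert out[2, 2] == frame[2, 2]


def test_empty_mask_warns_and_fills_global_mean(rng):
    frame = rng.random((10, 10))
    with pytest.warns(UserWarning):
        out = sf.normalize_background(frame, np.zeros((10, 10), bool))
    assert np.allclose(out, frame.mean())


# -- brightness equalization -----------------------------------------------


def test_mean_at_gamma_is_fixed_point():
    frame = np.full((10, 10), 0.5)
    np.testing.assert_allclose(sf.equalize_brightness(frame), frame)


def test_constant_quarter_converges_in_one_step():
    """ln(0.5)/ln(0.25) = 0.5, and 0.25^0.5 = 0.5 exactly."""
    out = sf.equalize_brightness(np.full((8, 8), 0.25))
    np.testing.assert_allclose(out, 0.5, atol=1e-9)


def test_random_frame_mean_reaches_gamma(rng):
    frame = np.clip(rng.random((40, 40)) * 0.5 + 0.1, 0.0, 1.0)
    out = sf.equalize_brightness(frame, gamma=0.5, tolerance=1e-3)
    assert abs(out.mean() - 0.5) <= 1e-3


def test_degenerate_frame_passes_through_with_warning():
    with pytest.warns(UserWarning):
        out = sf.equalize_brightness(np.zeros((5, 5)))
    assert (out == 0).all()


# -- dense optical flow -----------------------------------------------------


def test_identity_flow_is_zero(y_phantom):
    _, _, video, _ = y_phantom
    flow = sf.dense_flow(video[0], video[0])
    assert flow.magnitude.max() <= 0.05


def test_translation_recovered_in_magnitude_and_phase(y_phantom):
    """Textured (in-vessel) region translated by (0, 2): magnitude within
    10% of 2 px, phase within 10 degrees of the motion direction."""
    _, _, video, gt = y_phantom
    f1 = video[0]
    f2 = np.roll(f1, (0, 2), axis=(0, 1))
    flow = sf.dense_flow(f1, f2)
    textured = gt.mask & np.roll(gt.mask, (0, 2), axis=(0, 1))
    med = np.median(flow.magnitude[textured])
    assert abs(med - 2.0) / 2.0 < 0.10
    phases = flow.phase[textured][flow.magnitude[textured] > 1.0]
    ang_err = np.abs(np.angle(np.exp(1j * phases)))
    assert np.median(ang_err) < np.deg2rad(10)


def test_polar_view_consistent(y_phantom):
    _, _, video, _ = y_phantom
    flow = sf.dense_flow(video[0], video[1])
    np.testing.assert_allclose(
        flow.magnitude, np.hypot(flow.u, flow.v), atol=1e-6
    )
    assert flow.phase.min() >= 0.0 and flow.phase.max() < 2 * np.pi


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        sf.dense_flow(np.zeros((32, 32)), np.zeros((32, 48)))


# -- HSV rendering ----------------------------------------------------------


def test_zero_field_renders_black():
    flow = sf.FlowField(u=np.zeros((10, 10)), v=np.zeros((10, 10)))
    assert sf.flow_to_hsv(flow).max() == 0.0


def test_uniform_flow_single_hue(rng):
    flow = sf.FlowField(u=np.full((10, 10), 2.0), v=np.zeros((10, 10)))
    rgb = sf.flow_to_hsv(flow)
    assert np.allclose(rgb, rgb[0, 0])


def test_opposite_flows_have_opposite_hues():
    u = np.concatenate([np.full((10, 10), 2.0), np.full((10, 10), -2.0)])
    flow = sf.FlowField(u=u, v=np.zeros_like(u))
    hue_a = flow.phase[0, 0] / (2 * np.pi)
    hue_b = flow.phase[-1, 0] / (2 * np.pi)
    assert np.isclose(abs(hue_a - hue_b), 0.5)


# -- velocity profiles and widths -------------------------------------------


def test_zero_flow_zero_profile():
    flow = sf.FlowField(u=np.zeros((30, 40)), v=np.zeros((30, 40)))
    pix = np.column_stack([np.full(10, 15), np.arange(10, 20)])
    prof = sf.velocity_profile([flow], pix, np.arange(10, dtype=float))
    assert (prof.v_rel == 0).all()
    assert len(prof.s) == len(pix)


def test_profile_matches_phantom_speed(straight_tube_scene):
    video, gt = sf.render_video(straight_tube_scene, sf.MotionSpec(seed=1), [2.0], 8)
    norm = np.stack([sf.normalize_background(f, gt.mask, feather=2.0) for f in video])
    flows = [sf.dense_flow(norm[t], norm[t + 1]) for t in range(6)]
    skel = sf.skeletonize(gt.mask)
    seg = max(skel.segments, key=lambda s: s.length)
    prof = sf.velocity_profile(flows, seg.pixels, np.arange(len(seg.pixels), dtype=float))
    assert abs(np.median(prof.v_rel) - 2.0) / 2.0 <= 0.15


def test_profile_out_of_bounds_rejected():
    flow = sf.FlowField(u=np.zeros((20, 20)), v=np.zeros((20, 20)))
    pix = np.array([[5, 25]])
    with pytest.raises(ValueError):
        sf.velocity_profile([flow], pix, np.array([0.0]))


def test_ribbon_width_within_one_pixel():
    mask = np.zeros((40, 80), bool)
    mask[17:24, 5:75] = True  # 7 px wide
    pix = np.column_stack([np.full(50, 20), np.arange(15, 65)])
    w = sf.vessel_width(mask, pix)
    assert np.all(np.abs(w - 7) <= 1.0)
    assert w.std() <= 0.5


def test_single_pixel_line_width():
    mask = np.zeros((20, 40), bool)
    mask[10, 5:35] = True
    w = sf.vessel_width(mask, np.column_stack([np.full(10, 10), np.arange(12, 22)]))
    assert np.all((w >= 1.0) & (w <= 2.0))


def test_width_off_mask_rejected():
    mask = np.zeros((10, 10), bool)
    with pytest.raises(ValueError):
        sf.vessel_width(mask, np.array([[5, 5]]))


# -- volumetric speed and calibration ---------------------------------------


def test_zero_speed_zero_volume():
    S, Q = sf.volumetric_speed(0.0, 5.0)
    assert Q == 0.0 and S > 0


def test_volumetric_arithmetic():
    S, Q = sf.volumetric_speed(2.0, 2.0)
    assert np.isclose(S, np.pi) and np.isclose(Q, 2 * np.pi)


def test_nonpositive_width_rejected():
    with pytest.raises(ValueError):
        sf.volumetric_speed(1.0, 0.0)


@pytest.mark.parametrize(
    "v_rel, um, fps, expected",
    [(1.0, 1.0, 1.0, 1e-6), (0.0, 2.0, 30.0, 0.0), (10.0, 2.5, 100.0, 2.5e-3)],
)
def test_calibration_unit_chain(v_rel, um, fps, expected):
    assert np.isclose(sf.calibrate(v_rel, um, fps), expected)


def test_calibration_requires_positive_constants():
    with pytest.raises(ValueError):
        sf.calibrate(1.0, 0.0, 30.0)
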