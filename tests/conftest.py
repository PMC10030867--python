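"""Shared fixtures: small phantom scenes rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

import scleraflow as sf


@pytest.fixture(scope="session")
def y_phantom():
    """A single-bifurcation tree with conserved flow, static camera."""
    scene = sf.make_vessel_tree(2, seed=7, canvas=(160, 200))
    speeds = sf.assign_speeds(scene, v_root=2.5, conserve_flow=True)
    video, gt = sf.render_video(scene, sf.MotionSpec(seed=2), speeds, n_frames=10)
    return scene, speeds, video, gt


@pytest.fixture(scope="session")
def jittery_tree():
    """A 3-tip tree under 3 px/frame camera jitter, 60 frames."""
    scene = sf.make_vessel_tree(3, seed=3, canvas=(160, 200))
    speeds = sf.assign_speeds(scene, v_root=2.0, conserve_flow=True)
    video, gt = sf.render_video(
        scene, sf.MotionSpec(jitter_sd=3.0, seed=11), speeds, n_frames=60
    )
    return scene, speeds, video, gt


@pytest.fixture(scope="session")
def straight_tube_scene():
    """A single horizontal tube with generous margins on every side."""
    poly = np.array([[60.0, 30.0], [60.0, 210.0]])
    return sf.scene_from_polylines([poly], widths=8.0, canvas=(120, 240))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
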