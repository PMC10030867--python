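"""Vessel segmentation, binarization and the evaluation statistics."""

import numpy as np
import pytest

import scleraflow as sf


def test_blank_frame_is_all_non_vessel():
    P = sf.segment_vessels(np.full((64, 64), 0.5))
    assert P.min() >= 0.99
    assert not sf.binarize_mask(P).any()


def test_probability_map_bounded(rng):
    P = sf.segment_vessels(np.clip(rng.random((48, 48)), 0, 1))
    assert P.min() >= 0.0 and P.max() <= 1.0


def test_phantom_tube_dice(y_phantom):
    _, _, video, gt = y_phantom
    P = sf.segment_vessels(np.median(video.frames, axis=0))
    mask = sf.binarize_mask(P)
    assert sf.dice_coefficient(mask, gt.mask) >= 0.8


def test_bright_vessel_polarity(y_phantom):
    scene, speeds, _, _ = y_phantom
    import dataclasses

    bright = dataclasses.replace(scene, vessels_dark=False)
    video, gt = sf.render_video(bright, sf.MotionSpec(seed=2), speeds, 3)
    P = sf.segment_vessels(video[0], vessels_dark=False)
    assert sf.dice_coefficient(sf.binarize_mask(P), gt.mask) >= 0.8


def test_tiny_frame_rejected():
    with pytest.raises(ValueError):
        sf.segment_vessels(np.zeros((8, 8)))


def test_binarize_extremes():
    assert not sf.binarize_mask(np.ones((20, 20))).any()
    assert sf.binarize_mask(np.zeros((20, 20)), min_object_px=1).all()


def test_binarize_polarity_roundtrip(rng):
    """Inverting P with the complementary threshold flips the mask."""
    P = rng.random((30, 30))
    a = sf.binarize_mask(P, threshold=0.5, min_object_px=1)
    b = sf.binarize_mask(1.0 - P, threshold=0.5, min_object_px=1)
    # P exactly 0.5 belongs to neither side; exclude those pixels
    undecided = np.isclose(P, 0.5)
    assert not (a & b)[~undecided].any()
    assert (a | b)[~undecided].all()


def test_translation_equivariance_interior():
    """Shifting a border-quiet frame shifts the probability map with it."""
    import dataclasses

    scene = sf.make_vessel_tree(1, seed=5, canvas=(96, 128))
    # texture-free background: rolling must not change any border content,
    # or the global statistics the segmenter relies on would shift with it
    scene = dataclasses.replace(scene, background_texture=0.0)
    video, _ = sf.render_video(scene, sf.MotionSpec(seed=0), [0.0], 2)
    frame = video[0]
    shifted = np.roll(frame, (4, 7), axis=(0, 1))
    P1 = sf.segment_vessels(frame)
    P2 = sf.segment_vessels(shifted)
    inner = (slice(24, -24), slice(24, -24))
    np.testing.assert_allclose(np.roll(P1, (4, 7), axis=(0, 1))[inner], P2[inner], atol=1e-6)


def test_seeded_phantom_suite_mean_dice():
    dices = []
    for seed in range(10):
        scene = sf.make_vessel_tree(1 + seed % 3, seed=seed, canvas=(160, 200))
        video, gt = sf.render_video(
            scene, sf.MotionSpec(seed=seed), sf.assign_speeds(scene, 2.0), 3
        )
        P = sf.segment_vessels(video[0])
        dices.append(sf.dice_coefficient(sf.binarize_mask(P), gt.mask))
    assert np.mean(dices) >= 0.8


# -- evaluation statistics --------------------------------------------------


def test_perfect_prediction_scores():
    truth = np.zeros((10, 10), bool)
    truth[3:7, 2:8] = True
    P = np.where(truth, 0.0, 1.0)
    ev = sf.evaluate_segmentation(truth, truth, P)
    assert ev.accuracy == 1.0 and ev.sigma == 0.0


def test_complement_prediction_zero_accuracy():
    truth = np.zeros((6, 6), bool)
    truth[:3] = True
    ev = sf.evaluate_segmentation(~truth, truth)
    assert ev.accuracy == 0.0


def test_sigma_four_pixel_hand_oracle():
    """Labels (0,0,1,1) vs P (0.1,0.2,0.8,0.9): sigma = sqrt(0.10/4)."""
    pred = np.array([[True, True, False, False]])  # label 0 = vessel
    truth = pred.copy()
    P = np.array([[0.1, 0.2, 0.8, 0.9]])
    ev = sf.evaluate_segmentation(pred, truth, P)
    assert np.isclose(ev.sigma, np.sqrt((0.01 + 0.04 + 0.04 + 0.01) / 4))
    assert ev.accuracy == 1.0


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        sf.evaluate_segmentation(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


# -- optional patch classifier ---------------------------------------------


def test_patch_classifier_learns_phantom_vessels():
    frames, masks = [], []
    for seed in range(3):
        scene = sf.make_vessel_tree(2, seed=seed, canvas=(128, 160))
        video, gt = sf.render_video(
            scene, sf.MotionSpec(seed=seed), sf.assign_speeds(scene, 2.0), 2
        )
        frames.append(video[0])
        masks.append(gt.mask)
    clf = sf.PatchClassifier(patch_size=16, stride=4, seed=0).fit(
        frames, masks, n_patches_per_frame=60
    )
    scene = sf.make_vessel_tree(2, seed=9, canvas=(128, 160))
    video, gt = sf.render_video(scene, sf.MotionSpec(seed=9), sf.assign_speeds(scene, 2.0), 2)
    P = sf.segment_vessels(video[0], method="patch_classifier", classifier=clf)
    assert P.shape == video[0].shape
    assert P.min() >= 0.0 and P.max() <= 1.0
    acc = sf.evaluate_segmentation(sf.binarize_mask(P, min_object_px=10), gt.mask).accuracy
    # far better than always guessing the majority class
    assert acc > max(gt.mask.mean(), 1 - gt.mask.mean()) - 0.05 and acc > 0.8


def test_untrained_classifier_rejected():
    with pytest.raises(ValueError):
        sf.segment_vessels(np.zeros((64, 64)), method="patch_classifier")
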