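"""Cropping, masking, normalization, resizing, augmentation."""

import numpy as np
import pytest

from cinescar import compute_bbox, make_c_channel, normalize, resize
from cinescar.io import myocardium_mask, rasterize_mask
from cinescar.preprocess import AugmentDraw, apply_augmentation, augment, crop, draw_augmentation


# --------------------------------------------------------------------------
# bounding box
# --------------------------------------------------------------------------

def test_single_pixel_mask_with_margin():
    mask = np.zeros((64, 64), dtype=bool)
    mask[30, 40] = True
    bbox = compute_bbox(mask, margin_px=4)
    assert (bbox.row0, bbox.col0, bbox.side) == (26, 36, 9)


def test_rectangular_extent_squarized_about_centre():
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:30, 20:30] = True  # 20 rows x 10 cols
    bbox = compute_bbox(mask, margin_px=0)
    assert bbox.side == 20
    assert bbox.row0 == 10
    assert bbox.col0 == 15  # columns centred: 10 extra split 5/5


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        compute_bbox(np.zeros((16, 16), dtype=bool))


def test_bbox_contains_every_mask_pixel(normal_phantom):
    loop, contours, _ = normal_phantom
    epi = rasterize_mask(contours.epi[0], loop.shape)
    bbox = compute_bbox(epi, margin_px=4)
    rows, cols = np.nonzero(epi)
    assert (rows >= bbox.row0).all() and (rows < bbox.row0 + bbox.side).all()
    assert (cols >= bbox.col0).all() and (cols < bbox.col0 + bbox.side).all()


def test_bbox_clamped_to_frame_near_border():
    mask = np.zeros((32, 32), dtype=bool)
    mask[0:4, 0:4] = True
    bbox = compute_bbox(mask, margin_px=6)
    assert bbox.row0 >= 0 and bbox.col0 >= 0
    assert bbox.row0 + bbox.side <= 32 and bbox.col0 + bbox.side <= 32


# --------------------------------------------------------------------------
# C channel
# --------------------------------------------------------------------------

def test_c_channel_annulus_of_ones(normal_phantom):
    loop, contours, _ = normal_phantom
    myo = myocardium_mask(contours, 0, loop.shape)
    bbox = compute_bbox(rasterize_mask(contours.epi[0], loop.shape), 2)
    c = make_c_channel(np.ones(loop.shape), myo, bbox)
    cropped_mask = crop(myo.astype(float), bbox)
    np.testing.assert_array_equal(c.data, cropped_mask)


def test_c_channel_nonzero_count_equals_mask_bbox_intersection(normal_phantom):
    loop, contours, _ = normal_phantom
    myo = myocardium_mask(contours, 0, loop.shape)
    bbox = compute_bbox(rasterize_mask(contours.epi[0], loop.shape), 4)
    frame = loop.frames[0]
    c = make_c_channel(frame, myo, bbox)
    rs, cs = bbox.slices()
    expected = np.count_nonzero(myo[rs, cs] & (frame[rs, cs] != 0))
    assert np.count_nonzero(c.data) == expected


def test_empty_intersection_warns_and_zeroes():
    frame = np.ones((32, 32))
    mask = np.zeros((32, 32), dtype=bool)
    mask[0, 0] = True
    from cinescar.preprocess import BoundingBox

    with pytest.warns(UserWarning):
        c = make_c_channel(frame, np.zeros((32, 32), dtype=bool), BoundingBox(8, 8, 8))
    assert not c.data.any()


def test_out_of_frame_bbox_rejected():
    from cinescar.preprocess import BoundingBox

    with pytest.raises(ValueError):
        crop(np.zeros((16, 16)), BoundingBox(10, 10, 10))


# --------------------------------------------------------------------------
# normalize / resize
# --------------------------------------------------------------------------

def test_normalize_constant_and_two_pixel_toy():
    np.testing.assert_array_equal(normalize(np.full((5, 5), 3.3)), 0.0)
    np.testing.assert_allclose(normalize(np.array([[0.0, 2.0]])), [[-1.0, 1.0]])


def test_normalize_random_channel_statistics():
    rng = np.random.default_rng(0)
    out = normalize(rng.normal(50, 7, size=(224, 224)))
    assert abs(out.mean()) < 1e-6
    assert abs(out.std() - 1.0) < 1e-6


def test_resize_identity_and_constant():
    rng = np.random.default_rng(1)
    x = rng.random((224, 224))
    np.testing.assert_allclose(resize(x, 224), x, atol=1e-12)
    np.testing.assert_allclose(resize(np.full((64, 64), 2.5), 32), 2.5)


def test_resize_ramp_stays_linear_without_overshoot():
    ramp = np.tile(np.linspace(0.0, 1.0, 64), (64, 1))
    out = resize(ramp, 32)
    # bilinear interpolation is convex: no value leaves the input range
    assert out.min() >= 0.0 - 1e-12 and out.max() <= 1.0 + 1e-12
    # each output row is an affine ramp (constant second difference)
    second_diff = np.diff(out[0], n=2)
    np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def test_identity_draw_returns_input_unchanged():
    rng = np.random.default_rng(0)
    sample = rng.random((3, 32, 32))
    out = apply_augmentation(sample, AugmentDraw(False, False, 0.0, 0.0, 0.0))
    np.testing.assert_array_equal(out, sample)


def test_flips_are_involutions():
    rng = np.random.default_rng(1)
    sample = rng.random((2, 16, 16))
    draw = AugmentDraw(True, True, 0.0, 0.0, 0.0)
    twice = apply_augmentation(apply_augmentation(sample, draw), draw)
    np.testing.assert_array_equal(twice, sample)


def test_zero_sample_stays_zero_for_any_draw():
    rng = np.random.default_rng(2)
    sample = np.zeros((4, 24, 24))
    for _ in range(5):
        draw = draw_augmentation(rng, side=24)
        assert not apply_augmentation(sample, draw).any()


def test_channels_stay_geometrically_aligned():
    """A marker pixel must land at identical coordinates in every channel."""
    rng = np.random.default_rng(3)
    sample = np.zeros((3, 33, 33))
    sample[:, 16, 16] = 0.5
    sample[:, 8, 20] = 1.0  # off-centre marker
    for _ in range(10):
        draw = draw_augmentation(rng, side=33)
        out = apply_augmentation(sample, draw)
        pos = [np.unravel_index(np.argmax(out[c]), out[c].shape) for c in range(3)]
        assert pos[0] == pos[1] == pos[2]


def test_draw_ranges_respected():
    rng = np.random.default_rng(4)
    for _ in range(100):
        d = draw_augmentation(rng, side=100, shift_frac=0.2, rot_deg=20.0)
        assert -20.0 <= d.shift_x <= 20.0
        assert -20.0 <= d.shift_y <= 20.0
        assert -20.0 <= d.rot_deg <= 20.0


def test_augment_draws_are_rng_driven_and_reproducible():
    sample = np.random.default_rng(5).random((2, 32, 32))
    out1 = augment(sample, np.random.default_rng(77))
    out2 = augment(sample, np.random.default_rng(77))
    np.testing.assert_array_equal(out1, out2)
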