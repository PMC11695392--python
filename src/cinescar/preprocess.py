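"""Cropping, myocardial masking, normalization, resizing and augmentation.

The fixed pipeline order is: parametric images are computed on full frames,
then every channel of a slice is cropped with the same square LV bounding
box, normalized per channel (zero mean, unit SD over that channel's pixels),
resized to the network input side, and stacked.  Only the cine channel C is
myocardium-masked; the parametric channels keep their full cropped content
(a ``mask_all_channels`` switch enables the alternative).  Augmentation
(flips, shifts up to 20% of the side, rotations up to 20 degrees) is applied
with one shared draw across all channels of a sample, training set only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import SimilarityTransform, resize as _sk_resize, warp

from .fourier import ParametricImage


@dataclass(frozen=True)
class BoundingBox:
    """Square crop in source-pixel coordinates, half-open rows/cols."""

    row0: int
    col0: int
    side: int

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.side),
            slice(self.col0, self.col0 + self.side),
        )


def compute_bbox(epi_mask: np.ndarray, margin_px: int = 4) -> BoundingBox:
    """Tight square bounding box of the epicardial mask plus a margin.

    The tight row/col extent is expanded by ``margin_px`` on every side,
    symmetrized to a square by enlarging the shorter dimension about its
    centre, then clamped (by shifting, and as a last resort shrinking) to
    the frame.
    """
    epi_mask = np.asarray(epi_mask, dtype=bool)
    if not epi_mask.any():
        raise ValueError("cannot compute a bounding box of an empty mask")
    rows = np.flatnonzero(epi_mask.any(axis=1))
    cols = np.flatnonzero(epi_mask.any(axis=0))
    r0, r1 = rows[0] - margin_px, rows[-1] + margin_px + 1
    c0, c1 = cols[0] - margin_px, cols[-1] + margin_px + 1
    height, width = r1 - r0, c1 - c0
    side = max(height, width)
    # enlarge the shorter dimension about its centre
    r0 -= (side - height) // 2
    c0 -= (side - width) // 2
    H, W = epi_mask.shape
    side = min(side, H, W)
    r0 = int(np.clip(r0, 0, H - side))
    c0 = int(np.clip(c0, 0, W - side))
    return BoundingBox(row0=r0, col0=c0, side=int(side))


def crop(channel: np.ndarray, bbox: BoundingBox) -> np.ndarray:
    """Crop a 2-D channel with a bounding box that must fit the frame."""
    H, W = channel.shape
    if bbox.row0 < 0 or bbox.col0 < 0 or bbox.row0 + bbox.side > H or bbox.col0 + bbox.side > W:
        raise ValueError(f"bounding box {bbox} exceeds frame shape {(H, W)}")
    rs, cs = bbox.slices()
    return np.asarray(channel, dtype=float)[rs, cs]


def make_c_channel(
    ed_frame: np.ndarray, myo_mask: np.ndarray, bbox: BoundingBox
) -> ParametricImage:
    """Myocardium-masked, cropped ED cine frame (the static channel C)."""
    ed_frame = np.asarray(ed_frame, dtype=float)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if ed_frame.shape != myo_mask.shape:
        raise ValueError("frame and myocardium mask must share a shape")
    masked = np.where(myo_mask, ed_frame, 0.0)
    data = crop(masked, bbox)
    if not np.any(data):
        warnings.warn("C channel is identically zero (empty mask/bbox intersection)")
    return ParametricImage(data, "C")


def normalize(channel: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD normalization over all pixels of the channel.

    A constant channel maps to all zeros (the SD is floored at 1e-8).
    """
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    if np.ptp(channel) == 0:
        return np.zeros_like(channel)
    mean = channel.mean()
    std = channel.std()
    return (channel - mean) / max(std, 1e-8)


def resize(channel: np.ndarray, out_side: int = 224) -> np.ndarray:
    """Bilinear resize to out_side x out_side (identity if already there)."""
    channel = np.asarray(channel, dtype=float)
    if channel.shape == (out_side, out_side):
        return channel.copy()
    return _sk_resize(
        channel,
        (out_side, out_side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


@dataclass(frozen=True)
class AugmentDraw:
    """One realisation of the augmentation parameters."""

    flip_h: bool
    flip_v: bool
    shift_x: float  # pixels
    shift_y: float
    rot_deg: float

    @property
    def is_identity(self) -> bool:
        return (
            not self.flip_h
            and not self.flip_v
            and self.shift_x == 0.0
            and self.shift_y == 0.0
            and self.rot_deg == 0.0
        )


def draw_augmentation(
    rng: np.random.Generator,
    side: int,
    shift_frac: float = 0.2,
    rot_deg: float = 20.0,
) -> AugmentDraw:
    """Sample one augmentation: flips (p=0.5 each axis), shifts in
    +/-[0, shift_frac]*side, rotation in +/-[0, rot_deg] degrees."""
    return AugmentDraw(
        flip_h=bool(rng.random() < 0.5),
        flip_v=bool(rng.random() < 0.5),
        shift_x=float(rng.uniform(-shift_frac, shift_frac) * side),
        shift_y=float(rng.uniform(-shift_frac, shift_frac) * side),
        rot_deg=float(rng.uniform(-rot_deg, rot_deg)),
    )


def apply_augmentation(sample: np.ndarray, draw: AugmentDraw) -> np.ndarray:
    """Apply one augmentation draw identically to every channel.

    ``sample`` is an (n_channels, side, side) stack; geometry stays aligned
    across channels because a single transform is reused.  Out-of-frame
    pixels are filled with 0.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 3 or sample.shape[1] != sample.shape[2]:
        raise ValueError("sample must be (n_channels, side, side)")
    if draw.is_identity:
        return sample.copy()
    side = sample.shape[1]
    out = sample
    if draw.flip_h:
        out = out[:, :, ::-1]
    if draw.flip_v:
        out = out[:, ::-1, :]
    centre = (side - 1) / 2.0
    # rotate about the image centre, then translate
    tform = (
        SimilarityTransform(translation=(-centre, -centre))
        + SimilarityTransform(rotation=math.radians(draw.rot_deg))
        + SimilarityTransform(translation=(centre + draw.shift_x, centre + draw.shift_y))
    )
    if draw.rot_deg == 0.0 and draw.shift_x == 0.0 and draw.shift_y == 0.0:
        return np.ascontiguousarray(out)
    warped = np.stack(
        [
            warp(ch, tform.inverse, order=1, cval=0.0, preserve_range=True)
            for ch in out
        ]
    )
    return warped


def augment(
    sample: np.ndarray,
    rng: np.random.Generator,
    shift_frac: float = 0.2,
    rot_deg: float = 20.0,
) -> np.ndarray:
    """Draw and apply one random augmentation to an n-channel sample."""
    draw = draw_augmentation(rng, side=np.asarray(sample).shape[-1],
                             shift_frac=shift_frac, rot_deg=rot_deg)
    return apply_augmentation(sample, draw)
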