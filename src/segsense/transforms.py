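"""Deterministic, parametrized image transformations with explicit mask policy.

Each transform is registered as a :class:`TransformSpec` that records, next
to the image operation itself, whether the ground-truth mask must be
co-transformed.  Geometric transforms (rotation, dihedral flips, crop, zoom,
resize) carry an ``apply_mask`` so that scoring happens in the transformed
frame; intensity transforms (brightness, contrast, k-space spikes) leave the
mask untouched.  Images are interpolated bilinearly, masks always with
nearest-neighbor so integer labels are preserved and never invented.

Conventions: rotation angles are degrees *clockwise* in the usual raster
display (origin top-left); multiples of 90 degrees are executed exactly via
axis permutation rather than interpolation; regions moved off-canvas are
filled with 0 (black background and the background class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .core import GrayImage, LabelMask, Sample

__all__ = [
    "TransformSpec",
    "rotate",
    "dihedral",
    "crop",
    "zoom",
    "resize",
    "adjust_brightness",
    "adjust_contrast",
    "rotate_image",
    "rotate_mask",
    "resize_mask_to",
    "build_registry",
]


@dataclass(frozen=True)
class TransformSpec:
    """A named parametrized transform plus its mask co-transformation policy.

    ``apply_mask`` is present exactly for geometric transforms; for intensity
    transforms it is ``None`` and the engine scores against the original mask.
    ``neutral_value`` is the parameter at which the transform is the identity.
    """

    name: str
    apply_image: Callable[[GrayImage, Any], GrayImage]
    apply_mask: Optional[Callable[[LabelMask, Any], LabelMask]]
    param_name: str
    default_grid: tuple
    neutral_value: Any

    @property
    def is_geometric(self) -> bool:
        return self.apply_mask is not None

    def apply(self, sample: Sample, value: Any) -> Sample:
        """Transform a sample: the image always, the mask per policy."""
        image = self.apply_image(sample.image, value)
        mask = sample.mask
        if mask is not None and self.apply_mask is not None:
            mask = self.apply_mask(mask, value)
        return Sample(image=image, mask=mask)


# ---------------------------------------------------------------------------
# rotation and dihedral group
# ---------------------------------------------------------------------------

def rotate_image(image: GrayImage, angle: float) -> GrayImage:
    angle = float(angle)
    if angle % 90 == 0:
        # exact quarter-turns: no interpolation, bit-reproducible
        return GrayImage(np.rot90(image.pixels, k=-int(angle // 90) % 4).copy())
    out = ndimage.rotate(image.pixels, -angle, reshape=False, order=1, cval=0.0)
    return GrayImage(np.clip(out, 0.0, 1.0))


def rotate_mask(mask: LabelMask, angle: float) -> LabelMask:
    angle = float(angle)
    if angle % 90 == 0:
        return LabelMask(np.rot90(mask.labels, k=-int(angle // 90) % 4).copy(), mask.class_names)
    out = ndimage.rotate(mask.labels, -angle, reshape=False, order=0, cval=0)
    return LabelMask(out, mask.class_names)


def rotate(sample: Sample, angle: float) -> Sample:
    """Rotate image (bilinear) and mask (nearest) clockwise about the center.

    Output canvas size is preserved; exposed regions are filled with 0.
    """
    mask = rotate_mask(sample.mask, angle) if sample.mask is not None else None
    return Sample(rotate_image(sample.image, angle), mask)


def _dihedral_array(arr: np.ndarray, k: int) -> np.ndarray:
    if not 0 <= int(k) <= 7:
        raise ValueError(f"dihedral element k must be in 0..7, got {k}")
    k = int(k)
    out = np.flipud(arr) if k >= 4 else arr
    return np.rot90(out, k=-(k % 4)).copy()


def dihedral(sample: Sample, k: int) -> Sample:
    """Apply the k-th of the 8 symmetries of the square, exactly.

    k % 4 selects the clockwise quarter-turn count; k >= 4 additionally
    flips up/down (before rotating).  All 8 elements are pure axis
    permutations — no interpolation is involved.
    """
    image = GrayImage(_dihedral_array(sample.image.pixels, k))
    mask = None
    if sample.mask is not None:
        mask = LabelMask(_dihedral_array(sample.mask.labels, k), sample.mask.class_names)
    return Sample(image, mask)


# ---------------------------------------------------------------------------
# crop / zoom / resize
# ---------------------------------------------------------------------------

def _crop_array(arr: np.ndarray, size: int, center: tuple[int, int], cval) -> np.ndarray:
    size = int(size)
    if size < 1:
        raise ValueError(f"crop size must be >= 1, got {size}")
    out = np.full((size, size), cval, dtype=arr.dtype)
    r0 = int(center[0]) - size // 2
    c0 = int(center[1]) - size // 2
    src_r = slice(max(r0, 0), min(r0 + size, arr.shape[0]))
    src_c = slice(max(c0, 0), min(c0 + size, arr.shape[1]))
    dst_r = slice(src_r.start - r0, src_r.stop - r0)
    dst_c = slice(src_c.start - c0, src_c.stop - c0)
    if src_r.start < src_r.stop and src_c.start < src_c.stop:
        out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def crop(sample: Sample, size: int, center: Optional[tuple[int, int]] = None) -> Sample:
    """Extract a size x size window about ``center`` (default: image center).

    The window is zero-padded where it exceeds the image bounds, so sizes
    larger than the image embed it in a black border.  The mask is cropped
    identically.
    """
    h, w = sample.image.shape
    ctr = (h // 2, w // 2) if center is None else (int(center[0]), int(center[1]))
    image = GrayImage(_crop_array(sample.image.pixels, size, ctr, 0.0))
    mask = None
    if sample.mask is not None:
        mask = LabelMask(_crop_array(sample.mask.labels, size, ctr, 0), sample.mask.class_names)
    return Sample(image, mask)


def _zoom_array(arr: np.ndarray, scale: float, order: int, cval) -> np.ndarray:
    scale = float(scale)
    if scale <= 0:
        raise ValueError(f"zoom scale must be > 0, got {scale}")
    if scale == 1.0:
        return arr.copy()
    # center-fixed scaling on an unchanged canvas, via the inverse map
    center = (np.asarray(arr.shape, dtype=np.float64) - 1.0) / 2.0
    matrix = np.eye(2) / scale
    offset = center - matrix @ center
    out = ndimage.affine_transform(
        arr.astype(np.float64), matrix, offset=offset, order=order,
        cval=float(cval), output_shape=arr.shape, mode="constant",
    )
    return out.astype(arr.dtype) if order == 0 else out


def zoom(sample: Sample, scale: float) -> Sample:
    """Magnify (scale > 1) or shrink (scale < 1) about the center.

    Canvas size is unchanged: magnified content is clipped at the border,
    shrunk content is surrounded by zeros.  Image bilinear, mask nearest.
    """
    image = GrayImage(np.clip(_zoom_array(sample.image.pixels, scale, 1, 0.0), 0.0, 1.0))
    mask = None
    if sample.mask is not None:
        mask = LabelMask(_zoom_array(sample.mask.labels, scale, 0, 0), sample.mask.class_names)
    return Sample(image, mask)


def resize_mask_to(mask: LabelMask, shape: tuple[int, int]) -> LabelMask:
    """Nearest-neighbor resample of a label mask to an arbitrary shape."""
    if mask.shape == tuple(shape):
        return mask
    out = _sk_resize(mask.labels, shape, order=0, anti_aliasing=False, preserve_range=True)
    return LabelMask(np.round(out).astype(np.int64), mask.class_names)


def resize(sample: Sample, size: int) -> Sample:
    """Resample to size x size: image bilinear, mask nearest-neighbor."""
    size = int(size)
    if size < 1:
        raise ValueError(f"resize target must be >= 1, got {size}")
    px = _sk_resize(sample.image.pixels, (size, size), order=1,
                    anti_aliasing=False, preserve_range=True)
    image = GrayImage(np.clip(px, 0.0, 1.0))
    mask = resize_mask_to(sample.mask, (size, size)) if sample.mask is not None else None
    return Sample(image, mask)


# ---------------------------------------------------------------------------
# intensity transforms (mask untouched)
# ---------------------------------------------------------------------------

def adjust_brightness(sample: Sample, delta: float) -> Sample:
    """Additive intensity shift, clipped to [0, 1]; mask untouched."""
    px = np.clip(sample.image.pixels + float(delta), 0.0, 1.0)
    return Sample(GrayImage(px), sample.mask)


def adjust_contrast(sample: Sample, factor: float) -> Sample:
    """Affine contrast about mid-gray 0.5, clipped to [0, 1]; mask untouched."""
    factor = float(factor)
    if factor <= 0:
        raise ValueError(f"contrast factor must be > 0, got {factor}")
    px = np.clip(0.5 + factor * (sample.image.pixels - 0.5), 0.0, 1.0)
    return Sample(GrayImage(px), sample.mask)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _img_op(fn: Callable[[Sample, Any], Sample]) -> Callable[[GrayImage, Any], GrayImage]:
    return lambda image, v: fn(Sample(image), v).image


def _mask_op(fn: Callable[[Sample, Any], Sample]) -> Callable[[LabelMask, Any], LabelMask]:
    def apply(mask: LabelMask, v):
        dummy = GrayImage(np.zeros(mask.shape))
        return fn(Sample(dummy, mask), v).mask

    return apply


def build_registry() -> dict[str, TransformSpec]:
    """All built-in transforms, addressable by name.

    Default grids cover the qualitative regimes of interest at desk scale:
    a full turn of rotations in 45-degree steps, the whole dihedral group,
    sizes spanning the collapse/stable/collapse regimes, moderate brightness
    and contrast excursions, and crop fractions down to a quarter of the
    short side.
    """
    from .artifacts import spike_spec  # deferred: artifacts imports this module's types

    specs = [
        TransformSpec(
            name="rotate", apply_image=_img_op(rotate), apply_mask=_mask_op(rotate),
            param_name="angle_deg_cw",
            default_grid=tuple(range(0, 361, 45)), neutral_value=0,
        ),
        TransformSpec(
            name="dihedral", apply_image=_img_op(dihedral), apply_mask=_mask_op(dihedral),
            param_name="k", default_grid=tuple(range(8)), neutral_value=0,
        ),
        TransformSpec(
            name="flip", apply_image=_img_op(dihedral), apply_mask=_mask_op(dihedral),
            param_name="k", default_grid=(0, 4), neutral_value=0,
        ),
        TransformSpec(
            name="crop", apply_image=_img_op(crop), apply_mask=_mask_op(crop),
            param_name="size_px", default_grid=(), neutral_value=None,
        ),
        TransformSpec(
            name="zoom", apply_image=_img_op(zoom), apply_mask=_mask_op(zoom),
            param_name="scale", default_grid=(0.5, 0.75, 1.0, 1.25, 1.5, 2.0),
            neutral_value=1.0,
        ),
        TransformSpec(
            name="resize", apply_image=_img_op(resize), apply_mask=_mask_op(resize),
            param_name="size_px",
            default_grid=(16, 32, 64, 100, 128, 256, 320, 512), neutral_value=None,
        ),
        TransformSpec(
            name="brightness", apply_image=_img_op(adjust_brightness), apply_mask=None,
            param_name="delta",
            default_grid=tuple(np.round(np.arange(-0.5, 0.5001, 0.125), 3)),
            neutral_value=0.0,
        ),
        TransformSpec(
            name="contrast", apply_image=_img_op(adjust_contrast), apply_mask=None,
            param_name="factor", default_grid=(0.25, 0.5, 1.0, 2.0, 4.0),
            neutral_value=1.0,
        ),
        spike_spec(),
    ]
    return {s.name: s for s in specs}


def registry_with_size_neutrals(sample: Sample) -> dict[str, TransformSpec]:
    """Registry where size-dependent transforms get grids/neutrals for ``sample``.

    ``crop`` and ``resize`` have no universal neutral value: identity is
    cropping/resizing to the current size.  This helper fills the neutral
    value and a crop grid as fractions {1.0, 0.75, 0.5, 0.25} of the short
    side of the given sample.
    """
    reg = build_registry()
    short = min(sample.image.shape)
    crop_grid = tuple(sorted({max(1, int(round(f * short))) for f in (1.0, 0.75, 0.5, 0.25)},
                             reverse=True))
    reg["crop"] = TransformSpec(
        name="crop", apply_image=reg["crop"].apply_image, apply_mask=reg["crop"].apply_mask,
        param_name="size_px", default_grid=crop_grid, neutral_value=short,
    )
    reg["resize"] = TransformSpec(
        name="resize", apply_image=reg["resize"].apply_image,
        apply_mask=reg["resize"].apply_mask, param_name="size_px",
        default_grid=reg["resize"].default_grid, neutral_value=sample.image.shape[0],
    )
    return reg
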