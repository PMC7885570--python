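"""Domain types and image/mask I/O.

The central objects are :class:`GrayImage` (a 2-D float intensity array
normalized to [0, 1]), :class:`LabelMask` (a 2-D integer class map with an
ordered class-name vocabulary, index 0 reserved for background) and
:class:`SegmentationModel`, the adapter contract through which arbitrary
segmentation models — regardless of framework — are plugged into the sweep
engine.  A model only has to expose a prediction function mapping a
GrayImage to a LabelMask of the same shape; an optional size-preparation
function may run first when the model requires a specific input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GrayImage",
    "LabelMask",
    "Sample",
    "SegmentationModel",
    "ContractViolationError",
    "MaskMappingError",
    "UnsupportedInputError",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "wrap_model",
]


class ContractViolationError(ValueError):
    """A wrapped model broke the prediction contract (e.g. shape mismatch)."""


class MaskMappingError(ValueError):
    """A mask contained raw pixel values not covered by the value map."""


class UnsupportedInputError(ValueError):
    """An input file is readable but outside the supported formats."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with float intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMask:
    """A 2-D integer label map; ``class_names[0]`` is the background class."""

    labels: np.ndarray
    class_names: tuple[str, ...] = ("BG", "LV", "MY", "RV")

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"LabelMask requires a 2-D array, got shape {lab.shape}")
        lab = lab.astype(np.int64, copy=False)
        names = tuple(self.class_names)
        if lab.size and (lab.min() < 0 or lab.max() >= len(names)):
            bad = sorted(set(np.unique(lab)) - set(range(len(names))))
            raise MaskMappingError(
                f"label values {bad} are not valid indices into class_names "
                f"(length {len(names)})"
            )
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "class_names", names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def foreground_names(self) -> tuple[str, ...]:
        return self.class_names[1:]


@dataclass(frozen=True)
class Sample:
    """An image with an optional paired ground-truth mask."""

    image: GrayImage
    mask: Optional[LabelMask] = None

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.image.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


@dataclass
class SegmentationModel:
    """Adapter contract around an arbitrary segmentation model.

    ``predict`` maps a GrayImage to a LabelMask of the same shape; hard
    labels are required, so any argmax over soft outputs happens inside the
    user's function.  ``prepare_size``, when given, is applied by the engine
    before prediction (e.g. padding to the input size a network expects).
    """

    predict_fn: Callable[[GrayImage], LabelMask]
    prepare_size: Optional[Callable[[GrayImage], GrayImage]] = None
    name: str = "model"

    def predict(self, image: GrayImage) -> LabelMask:
        pred = self.predict_fn(image)
        if not isinstance(pred, LabelMask):
            raise ContractViolationError(
                f"model {self.name!r} returned {type(pred).__name__}, "
                "expected a LabelMask"
            )
        if pred.shape != image.shape:
            raise ContractViolationError(
                f"model {self.name!r} returned mask of shape {pred.shape} "
                f"for an image of shape {image.shape}"
            )
        return pred


def wrap_model(
    predict_fn: Callable[[GrayImage], LabelMask],
    prepare_size_fn: Optional[Callable[[GrayImage], GrayImage]] = None,
    name: str = "model",
) -> SegmentationModel:
    """Wrap a plain prediction function into the :class:`SegmentationModel` contract."""
    return SegmentationModel(predict_fn=predict_fn, prepare_size=prepare_size_fn, name=name)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return np.load(path)
    if suffix in (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    if suffix in (".dcm", ".dicom"):
        import pydicom

        return np.asarray(pydicom.dcmread(path).pixel_array)
    if suffix in (".nii", ".gz"):
        import nibabel as nib

        return np.asarray(nib.load(path).get_fdata())
    raise UnsupportedInputError(f"unsupported image format: {path}")


def _to_single_slice(arr: np.ndarray, path: Path) -> np.ndarray:
    """Reduce to a single 2-D slice; reject genuine volumes."""
    arr = np.atleast_2d(arr)
    while arr.ndim > 2 and 1 in arr.shape:  # trailing/leading singleton dims
        arr = arr.reshape([s for s in arr.shape if s != 1] or [1])
        arr = np.atleast_2d(arr)
    if (arr.ndim == 3 and arr.shape[-1] in (3, 4)
            and arr.shape[-1] < min(arr.shape[:2])):  # RGB(A) -> luminance
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.2126, 0.7152, 0.0722])
    if arr.ndim != 2:
        raise UnsupportedInputError(
            f"{path} has shape {arr.shape}; only single 2-D slices are "
            "supported (multi-slice volumes must be split upstream)"
        )
    return arr


def load_image(path: str | Path, normalize: bool = True) -> GrayImage:
    """Read a 2-D grayscale image from PNG/NPY (or a single DICOM/NIfTI slice).

    Multi-channel inputs are converted to luminance.  With ``normalize``
    (default) intensities are min–max rescaled to [0, 1]; a constant image
    maps to all zeros.  Without it, integer data is divided by its dtype
    maximum and float data clipped, so pixels always land in [0, 1].
    Orientation metadata of DICOM/NIfTI is deliberately not applied:
    orientation mismatch is itself an object of study here.
    """
    path = Path(path)
    raw = _read_array(path)
    arr = _to_single_slice(raw, path).astype(np.float64)
    if normalize:
        lo, hi = float(arr.min()), float(arr.max())
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    elif np.issubdtype(raw.dtype, np.integer):
        arr = np.clip(arr / float(np.iinfo(raw.dtype).max), 0.0, 1.0)
    else:
        arr = np.clip(arr, 0.0, 1.0)
    return GrayImage(arr)


def save_image(image: GrayImage, path: str | Path) -> Path:
    """Write a GrayImage as NPY (lossless) or 8-bit PNG."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, image.pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, np.round(np.clip(image.pixels, 0, 1) * 255).astype(np.uint8))
    return path


def load_mask(
    path: str | Path,
    class_names: Sequence[str] = ("BG", "LV", "MY", "RV"),
    value_map: Optional[Mapping[int, int]] = None,
) -> LabelMask:
    """Read an integer label mask, optionally mapping raw pixel values to class indices.

    Raw values must either already be valid indices into ``class_names`` or
    be covered by ``value_map`` (raw value -> class index).
    """
    path = Path(path)
    raw = _to_single_slice(_read_array(path), path)
    raw = np.round(raw).astype(np.int64)
    if value_map is not None:
        out = np.full_like(raw, -1)
        for src, dst in value_map.items():
            out[raw == int(src)] = int(dst)
        unmapped = sorted(set(np.unique(raw[out < 0])))
        if unmapped:
            raise MaskMappingError(
                f"mask values {unmapped} in {path} are not covered by the value map"
            )
        raw = out
    bad = sorted(v for v in np.unique(raw) if v < 0 or v >= len(class_names))
    if bad:
        raise MaskMappingError(
            f"mask values {bad} in {path} are not valid class indices "
            f"(expected 0..{len(class_names) - 1}); supply a value_map"
        )
    return LabelMask(raw, tuple(class_names))


def save_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a LabelMask as NPY or 8-bit PNG of raw class indices."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, mask.labels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, mask.labels.astype(np.uint8))
    return path
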