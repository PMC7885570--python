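"""Synthetic cardiac phantom and analytic oracle segmenters.

The phantom emulates a short-axis cardiac MR slice at the level of geometry
only: a bright disk for the left-ventricular blood pool (LV), an annulus of
myocardium (MY) around it, and a lateral blob for the right ventricle (RV),
on a dark background — so all three tissue classes exist with unequal areas.
The paired mask is the exact rasterization of the same geometry, which makes
every pipeline behavior testable without a trained network or external data.

Two reference models accompany it:

* ``threshold_oracle`` classifies each pixel by the nearest structure mean
  intensity.  Intensity thresholding commutes with geometric transforms, so
  it is the rotation-equivariant positive control: its sensitivity curves
  for rotations/flips/zoom are flat.  It is intentionally fragile under
  brightness/contrast changes, giving a non-trivial intensity curve.
* ``right_biased_oracle`` additionally suppresses all foreground predictions
  in the left half of the image — a built-in positional prior.  It
  reproduces, by construction, the failure mode of a model that expects the
  heart on one side of the image and keeps predicting it there even when the
  image is rotated by 180 degrees.

Structure intensities are ordered so that bilinear interpolation across any
spatially adjacent pair of the large structures passes through at most the
background/neighbor bins, keeping spurious third-class rings negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GrayImage, LabelMask, Sample, SegmentationModel

__all__ = ["PhantomSpec", "make_phantom", "threshold_oracle", "right_biased_oracle",
           "CLASS_NAMES"]

CLASS_NAMES: tuple[str, ...] = ("BG", "LV", "MY", "RV")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic short-axis phantom.

    center is in (row, col) fractions of the canvas; the default places the
    heart right of the image center.  radii are (lv_radius,
    myo_outer_radius) in pixels; rv_offset is the signed column offset of
    the RV blob from the heart center (negative = left, the usual display
    side).  intensities are per-structure means (BG, LV, MY, RV) in [0, 1],
    required to be separated by more than 4 * noise_sd so nearest-mean
    thresholding is a valid oracle.
    """

    size: int = 128
    center: tuple[float, float] = (0.5, 0.62)
    radii: tuple[float, float] = (16.0, 24.0)
    rv_offset: float = -30.0
    rv_radius: float = 12.0
    intensities: tuple[float, float, float, float] = (0.05, 0.65, 0.35, 0.95)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lv_r, myo_r = self.radii
        if not 0 < lv_r < myo_r < self.size / 2:
            raise ValueError(
                f"radii must satisfy 0 < lv_radius < myo_outer_radius < size/2, "
                f"got {self.radii} for size {self.size}"
            )
        vals = np.asarray(self.intensities, dtype=float)
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError(f"intensities must lie in [0, 1], got {self.intensities}")
        gaps = np.diff(np.sort(vals))
        if self.noise_sd < 0 or (len(gaps) and gaps.min() <= 4 * self.noise_sd):
            raise ValueError(
                f"intensities {self.intensities} must be pairwise separated by "
                f"more than 4 * noise_sd = {4 * self.noise_sd}"
            )

    def mirrored(self) -> "PhantomSpec":
        """The left-right mirrored spec (heart on the opposite side)."""
        return PhantomSpec(
            size=self.size, center=(self.center[0], 1.0 - self.center[1]),
            radii=self.radii, rv_offset=-self.rv_offset, rv_radius=self.rv_radius,
            intensities=self.intensities, noise_sd=self.noise_sd, seed=self.seed,
        )


def _geometry_mask(spec: PhantomSpec) -> np.ndarray:
    n = int(spec.size)
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    cr, cc = spec.center[0] * n, spec.center[1] * n
    lv_r, myo_r = spec.radii
    d_heart = np.hypot(rows - cr, cols - cc)
    d_rv = np.hypot(rows - cr, cols - (cc + spec.rv_offset))
    labels = np.zeros((n, n), dtype=np.int64)
    labels[d_rv < spec.rv_radius] = 3          # RV blob first …
    labels[d_heart < myo_r] = 2                # … annulus overrides its medial edge
    labels[d_heart < lv_r] = 1                 # LV blood pool innermost
    return labels


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Sample:
    """Generate the phantom image (with seeded Gaussian noise) and exact mask."""
    labels = _geometry_mask(spec)
    means = np.asarray(spec.intensities, dtype=np.float64)
    pixels = means[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    return Sample(GrayImage(pixels), LabelMask(labels, CLASS_NAMES))


def _classify_nearest(pixels: np.ndarray, means: np.ndarray) -> np.ndarray:
    # nearest structure mean per pixel; ties resolve to the lower class index
    dist = np.abs(pixels[..., None] - means[None, None, :])
    return np.argmin(dist, axis=-1).astype(np.int64)


def threshold_oracle(spec: PhantomSpec = PhantomSpec()) -> SegmentationModel:
    """Nearest-mean intensity classifier: exact on its own noiseless phantom.

    Pure per-pixel thresholding is equivariant under geometric transforms
    (the classification of a pixel does not depend on where it sits), so its
    Dice curves over rotations, flips and zoom stay flat.  It is deliberately
    sensitive to brightness/contrast changes, which move intensities across
    the fixed decision boundaries.
    """
    means = np.asarray(spec.intensities, dtype=np.float64)

    def predict(image: GrayImage) -> LabelMask:
        return LabelMask(_classify_nearest(image.pixels, means), CLASS_NAMES)

    return SegmentationModel(predict_fn=predict, name="threshold_oracle")


def right_biased_oracle(spec: PhantomSpec = PhantomSpec()) -> SegmentationModel:
    """Threshold classifier with a hard positional prior for the right half.

    All foreground predictions in the left half of the image are suppressed
    to background.  On a phantom whose heart sits entirely right of center
    it matches ``threshold_oracle`` exactly; once a rotation moves the heart
    to the left (e.g. 180 degrees), its heart-class Dice collapses.
    """
    means = np.asarray(spec.intensities, dtype=np.float64)

    def predict(image: GrayImage) -> LabelMask:
        labels = _classify_nearest(image.pixels, means)
        labels[:, : image.width // 2] = 0
        return LabelMask(labels, CLASS_NAMES)

    return SegmentationModel(predict_fn=predict, name="right_biased_oracle")
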