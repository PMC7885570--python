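"""MR k-space spike artifact simulation.

A spike artifact is a single corrupted sample of large magnitude in the
2-D spatial-frequency domain (k-space) of an MR image; in image space it
appears as a periodic stripe pattern whose spatial frequency is the spike's
k-space position.  The simulation here takes the centered 2-D DFT of the
image, adds a single complex spike whose magnitude is a stated multiple of
the maximum k-space magnitude (for ordinary images, the DC coefficient),
inverse-transforms and keeps the magnitude — mirroring MR magnitude
reconstruction — then clips back to [0, 1].

Spikes are an intensity corruption: the ground-truth mask is never
co-transformed.  A single spike (not a conjugate-symmetric pair) is
injected; users wanting a strictly real corruption can add the mirrored
spike themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrayImage

__all__ = [
    "SpikeParams",
    "add_kspace_spike",
    "spike_grid",
    "stripe_frequency",
    "spike_spec",
]


@dataclass(frozen=True)
class SpikeParams:
    """Position and strength of a k-space spike.

    offset_frac: fractional distance from the k-space center along ``axis``,
        0 = center (DC), 0.5 = edge of k-space.
    intensity_rel: spike magnitude as a multiple of the maximum k-space
        magnitude of the original image (dimensionless, >= 0).
    axis: frequency axis along which the offset is applied (0 = row
        frequency, 1 = column frequency).
    """

    offset_frac: float
    intensity_rel: float
    axis: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= float(self.offset_frac) <= 0.5:
            raise ValueError(f"offset_frac must be in [0, 0.5], got {self.offset_frac}")
        if float(self.intensity_rel) < 0:
            raise ValueError(f"intensity_rel must be >= 0, got {self.intensity_rel}")
        if int(self.axis) not in (0, 1):
            raise ValueError(f"axis must be 0 or 1, got {self.axis}")


def _spike_index(shape: tuple[int, int], params: SpikeParams) -> tuple[int, int]:
    center = (shape[0] // 2, shape[1] // 2)
    idx = list(center)
    ax = int(params.axis)
    idx[ax] = center[ax] + int(round(float(params.offset_frac) * shape[ax]))
    idx[ax] = min(idx[ax], shape[ax] - 1)
    return tuple(idx)


def add_kspace_spike(image: GrayImage, params: SpikeParams, clip: bool = True) -> GrayImage:
    """Corrupt an image with a single k-space spike.

    With ``clip=False`` the raw magnitude reconstruction is returned without
    re-clipping to [0, 1], which is useful for measuring the corruption
    energy itself.
    """
    k = np.fft.fftshift(np.fft.fft2(image.pixels))
    magnitude = float(params.intensity_rel) * float(np.abs(k).max())
    r, c = _spike_index(image.shape, params)
    k[r, c] += magnitude
    recon = np.abs(np.fft.ifft2(np.fft.ifftshift(k)))
    if clip:
        recon = np.clip(recon, 0.0, 1.0)
    return GrayImage(recon)


def spike_grid(
    image: GrayImage,
    offsets: list[float],
    intensities: list[float],
    axis: int = 0,
) -> list[list[GrayImage]]:
    """Cartesian product of corruptions: rows = offsets, columns = intensities."""
    if not offsets or not intensities:
        raise ValueError("offsets and intensities must be non-empty")
    return [
        [add_kspace_spike(image, SpikeParams(off, inten, axis)) for inten in intensities]
        for off in offsets
    ]


def stripe_frequency(original: GrayImage, corrupted: GrayImage) -> tuple[int, int]:
    """Dominant non-DC spatial frequency of the corruption, as |offsets| from center.

    Returns the centered-spectrum coordinates (|d_row|, |d_col|) of the
    strongest non-DC component of ``corrupted - original``.  Because the
    difference image is real its spectrum is conjugate-symmetric, so the
    magnitudes of the offsets identify the stripe frequency irrespective of
    which half-plane the peak lands in.
    """
    diff = corrupted.pixels - original.pixels
    spec = np.abs(np.fft.fftshift(np.fft.fft2(diff)))
    center = (diff.shape[0] // 2, diff.shape[1] // 2)
    spec[center] = 0.0  # the DC term is mean shift, not stripe frequency
    r, c = np.unravel_index(int(np.argmax(spec)), spec.shape)
    return abs(r - center[0]), abs(c - center[1])


def spike_spec():
    """Registry entry: spike as a transform over (offset_frac, intensity_rel) pairs.

    The default grid sweeps intensity at a fixed mid-range k-space offset;
    a spike of zero intensity is the neutral value (identity up to FFT
    round-trip error).  The mask policy is 'unchanged' (intensity corruption).
    """
    from .transforms import TransformSpec

    def apply_image(image: GrayImage, value) -> GrayImage:
        off, inten = value
        return add_kspace_spike(image, SpikeParams(float(off), float(inten)))

    grid = tuple((0.25, i) for i in (0.0, 0.01, 0.05, 0.1, 0.5, 1.0))
    return TransformSpec(
        name="spike", apply_image=apply_image, apply_mask=None,
        param_name="(offset_frac, intensity_rel)", default_grid=grid,
        neutral_value=(0.25, 0.0),
    )
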