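"""Rendering: mask overlays, static grids, animated GIFs, Dice-vs-parameter plots.

Overlays alpha-blend per-class colors onto the grayscale image; background is
left transparent unless requested.  Sweep results render either as a single
captioned panel grid (one panel per parameter value) or as an animated GIF
with the parameter value burned into each frame.  Sensitivity curves plot one
line per class with the y-axis pinned to [0, 1], so sharp peaks and plateaus
are visually comparable across transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .core import GrayImage, LabelMask
from .engine import SensitivityCurve, SweepResult

__all__ = ["OverlayStyle", "overlay", "render_grid", "render_gif", "plot_curve",
           "DEFAULT_PALETTE"]

# colorblind-safe palette (Okabe-Ito) for BG, LV, MY, RV; further classes cycle
DEFAULT_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.35, 0.35, 0.35),   # BG (only drawn when show_background)
    (0.90, 0.62, 0.00),   # LV orange
    (0.00, 0.62, 0.45),   # MY bluish green
    (0.34, 0.71, 0.91),   # RV sky blue
    (0.80, 0.47, 0.65),
    (0.94, 0.89, 0.26),
)


@dataclass(frozen=True)
class OverlayStyle:
    """Blending alpha, per-class colors and background visibility."""

    alpha: float = 0.5
    colormap: tuple[tuple[float, float, float], ...] = DEFAULT_PALETTE
    show_background: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    def color(self, class_index: int) -> tuple[float, float, float]:
        return self.colormap[class_index % len(self.colormap)]


def overlay(image: GrayImage, mask: LabelMask, style: OverlayStyle = OverlayStyle()) -> np.ndarray:
    """Alpha-blend class colors over the grayscale image; returns HxWx3 floats.

    Each labeled pixel becomes (1 - alpha) * gray + alpha * color — a convex
    combination, so channel values stay within [min, max] of the operands.
    Background pixels stay pure grayscale unless ``show_background``.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    rgb = np.repeat(image.pixels[..., None], 3, axis=-1)
    start = 0 if style.show_background else 1
    for idx in range(start, len(mask.class_names)):
        sel = mask.labels == idx
        if not sel.any():
            continue
        color = np.asarray(style.color(idx))
        rgb[sel] = (1.0 - style.alpha) * rgb[sel] + style.alpha * color
    return rgb


def _frame_rgb(frame, style: OverlayStyle) -> np.ndarray:
    return overlay(frame.image, frame.prediction, style)


def render_grid(
    result: SweepResult,
    path: str | Path,
    columns: int = 4,
    style: OverlayStyle = OverlayStyle(),
) -> Path:
    """One captioned panel per sweep frame, written as a single PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(result.frames)
    columns = max(1, min(int(columns), n))
    rows = math.ceil(n / columns)
    fig, axes = plt.subplots(rows, columns, figsize=(2.2 * columns, 2.4 * rows),
                             squeeze=False)
    for i, frame in enumerate(result.frames):
        ax = axes[i // columns][i % columns]
        ax.imshow(_frame_rgb(frame, style), interpolation="nearest")
        ax.set_title(f"{result.param_name}={frame.param_value}", fontsize=8)
        ax.axis("off")
    for j in range(n, rows * columns):
        axes[j // columns][j % columns].axis("off")
    fig.suptitle(result.transform_name)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def render_gif(
    result: SweepResult,
    path: str | Path,
    fps: float = 2.0,
    style: OverlayStyle = OverlayStyle(),
) -> Path:
    """Animated GIF, one frame per parameter value, caption burned in."""
    import imageio.v3 as iio
    from PIL import Image, ImageDraw

    frames = []
    for frame in result.frames:
        arr = np.round(np.clip(_frame_rgb(frame, style), 0, 1) * 255).astype(np.uint8)
        img = Image.fromarray(arr)
        draw = ImageDraw.Draw(img)
        caption = f"{result.param_name}={frame.param_value}"
        draw.text((2, 2), caption, fill=(255, 255, 255))
        frames.append(np.asarray(img))
    path = Path(path)
    iio.imwrite(path, frames, extension=".gif", duration=int(1000 / fps), loop=0)
    return path


def plot_curve(curve: SensitivityCurve, path: str | Path,
               transform_name: str = "", write_csv: bool = True) -> Path:
    """Dice vs parameter, one line per class, y fixed to [0, 1].

    A tidy CSV companion (transform, param, class, dice) is written next to
    the figure unless ``write_csv`` is disabled.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not curve.param_values:
        raise ValueError("cannot plot an empty curve")
    path = Path(path)
    x = list(range(len(curve.param_values)))
    labels = [repr(v) if isinstance(v, tuple) else v for v in curve.param_values]
    numeric = all(isinstance(v, (int, float)) for v in curve.param_values)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cls in curve.class_names:
        ys = [cs[cls] for cs in curve.scores]
        ax.plot(curve.param_values if numeric else x, ys, marker="o", label=cls)
    if not numeric:
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(curve.param_name)
    ax.set_ylabel("Dice")
    if transform_name:
        ax.set_title(transform_name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    if write_csv:
        curve.to_dataframe(transform_name).to_csv(path.with_suffix(".csv"), index=False)
    return path
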