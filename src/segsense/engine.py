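"""The sweep orchestrator.

A sweep applies one :class:`~segsense.transforms.TransformSpec` across a
parameter grid, runs the model on each transformed image, and collects the
(image, truth, prediction) triple per grid point.  Qualitative sweeps stop
there; quantitative sweeps additionally score each prediction with the
per-class Dice against the *co-transformed* ground truth — the central
bookkeeping rule: geometric transforms move the truth mask along with the
image so scoring happens in the transformed frame, while intensity
transforms score against the original, untouched mask.

When the model declares a size-preparation step, it is applied to the
transformed image before prediction, and the truth mask is resampled
(nearest-neighbor) to the prepared shape so the comparison stays consistent.
Sweeps are eager, sequential and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd

from .core import ContractViolationError, GrayImage, LabelMask, Sample, SegmentationModel
from .metrics import ClassScores, dice_per_class
from .transforms import TransformSpec, resize_mask_to

__all__ = ["Frame", "SensitivityCurve", "SweepResult",
           "qualitative_sweep", "quantitative_sweep", "baseline"]


@dataclass(frozen=True)
class Frame:
    """One grid point: the image fed to the model, the truth in the same frame
    (co-transformed for geometric transforms, original otherwise), and the
    model's prediction."""

    param_value: Any
    image: GrayImage
    truth: Optional[LabelMask]
    prediction: LabelMask


@dataclass(frozen=True)
class SensitivityCurve:
    """Per-class Dice as a function of a transformation parameter."""

    param_name: str
    param_values: tuple
    scores: tuple[ClassScores, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.param_values):
            raise ValueError("scores and param_values must have equal length")

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.scores[0].class_names if self.scores else ()

    def to_dataframe(self, transform_name: str = "") -> pd.DataFrame:
        rows = [
            {"transform": transform_name, "param": repr(v) if isinstance(v, tuple) else v,
             "class": cls, "dice": score}
            for v, cs in zip(self.param_values, self.scores)
            for cls, score in cs.items()
        ]
        return pd.DataFrame(rows, columns=["transform", "param", "class", "dice"])

    def range_per_class(self) -> dict[str, float]:
        """max - min of the Dice curve, per class."""
        out = {}
        for cls in self.class_names:
            vals = [cs[cls] for cs in self.scores]
            out[cls] = max(vals) - min(vals)
        return out


@dataclass(frozen=True)
class SweepResult:
    """All frames of one transform sweep, plus the curve when truth was given."""

    transform_name: str
    param_name: str
    param_values: tuple
    frames: tuple[Frame, ...]
    curve: Optional[SensitivityCurve] = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.param_values):
            raise ValueError("frames and param_values must have equal length")

    def curve_csv(self, path: str | Path) -> Path:
        if self.curve is None:
            raise ValueError("no curve: sweep was qualitative (no ground truth)")
        path = Path(path)
        self.curve.to_dataframe(self.transform_name).to_csv(path, index=False)
        return path


def _prepare_truth(model: SegmentationModel, truth: LabelMask,
                   target_shape: tuple[int, int]) -> LabelMask:
    """Carry the truth mask through the model's size preparation.

    Each class indicator image is passed through ``prepare_size`` and the
    per-pixel argmax taken, so the truth undergoes the same geometric
    mapping as the image whether the preparation pads, crops or resamples.
    All-zero regions (e.g. padding) argmax to the background class.
    """
    import numpy as np

    stacked = []
    for idx in range(len(truth.class_names)):
        indicator = GrayImage((truth.labels == idx).astype(float))
        stacked.append(model.prepare_size(indicator).pixels)
    labels = np.argmax(np.stack(stacked, axis=-1), axis=-1)
    prepared = LabelMask(labels, truth.class_names)
    if prepared.shape != target_shape:
        prepared = resize_mask_to(prepared, target_shape)
    return prepared


def _predict_frame(
    model: SegmentationModel,
    transformed: Sample,
    value: Any,
) -> Frame:
    image = transformed.image
    truth = transformed.mask
    if model.prepare_size is not None:
        image = model.prepare_size(image)
        if truth is not None and truth.shape != image.shape:
            truth = _prepare_truth(model, truth, image.shape)
    try:
        prediction = model.predict(image)
    except ContractViolationError as err:
        raise ContractViolationError(f"{err} (at parameter value {value!r})") from err
    return Frame(param_value=value, image=image, truth=truth, prediction=prediction)


def qualitative_sweep(
    model: SegmentationModel,
    sample: Sample,
    spec: TransformSpec,
    values: Optional[Sequence[Any]] = None,
) -> SweepResult:
    """Run the model across the transform's parameter grid; no scoring.

    For each grid value the image is transformed (and the mask, if present
    and the transform is geometric), size-prepared if the model asks for it,
    and predicted on.  ``values`` defaults to the spec's default grid.
    """
    grid = tuple(spec.default_grid if values is None else values)
    if not grid:
        raise ValueError(f"transform {spec.name!r} has no default grid; pass values")
    frames = tuple(
        _predict_frame(model, spec.apply(sample, v), v) for v in grid
    )
    return SweepResult(spec.name, spec.param_name, grid, frames, curve=None)


def quantitative_sweep(
    model: SegmentationModel,
    sample: Sample,
    spec: TransformSpec,
    values: Optional[Sequence[Any]] = None,
    include_background: bool = False,
) -> SweepResult:
    """As :func:`qualitative_sweep`, plus a per-class Dice curve.

    Requires ``sample.mask``.  The truth used at each grid point is the
    co-transformed mask for geometric transforms and the original mask for
    intensity transforms.
    """
    if sample.mask is None:
        raise ValueError("quantitative sweep requires a ground-truth mask")
    result = qualitative_sweep(model, sample, spec, values)
    scores = tuple(
        dice_per_class(f.prediction, f.truth, include_background=include_background)
        for f in result.frames
    )
    curve = SensitivityCurve(spec.param_name, result.param_values, scores)
    return SweepResult(result.transform_name, result.param_name,
                       result.param_values, result.frames, curve=curve)


def baseline(
    model: SegmentationModel,
    sample: Sample,
    include_background: bool = False,
) -> ClassScores:
    """Dice of the untransformed sample: the neutral-parameter reference."""
    if sample.mask is None:
        raise ValueError("baseline requires a ground-truth mask")
    frame = _predict_frame(model, sample, value=None)
    return dice_per_class(frame.prediction, frame.truth,
                          include_background=include_background)
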