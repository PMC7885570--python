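"""Per-class overlap scoring between predicted and ground-truth masks.

The Dice coefficient of class c is 2|A ∩ B| / (|A| + |B|) over the binary
supports A = {pred == c}, B = {truth == c}.  Degenerate classes follow the
usual convention: a class absent from both masks scores 1 (nothing to get
wrong), a class present in exactly one scores 0 (total miss) — the latter is
what makes a completely failed segmentation read as 0 across all classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import LabelMask

__all__ = ["ClassScores", "dice_per_class"]


@dataclass(frozen=True)
class ClassScores:
    """Mapping class-name -> Dice in [0, 1], one entry per reported class."""

    scores: Mapping[str, float]

    def __getitem__(self, name: str) -> float:
        return self.scores[name]

    def items(self):
        return self.scores.items()

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.scores.keys())

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(self.scores.values())


def dice_per_class(
    pred: LabelMask,
    truth: LabelMask,
    include_background: bool = False,
) -> ClassScores:
    """Dice score per class between a prediction and the ground truth.

    Background (class index 0) is excluded from the report by default, as
    only tissue classes are usually of interest.  Masks must share a shape;
    the class vocabulary is taken from the truth mask.
    """
    if pred.shape != truth.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}"
        )
    names = truth.class_names
    start = 0 if include_background else 1
    scores: dict[str, float] = {}
    for idx in range(start, len(names)):
        a = pred.labels == idx
        b = truth.labels == idx
        denom = int(a.sum()) + int(b.sum())
        if denom == 0:
            scores[names[idx]] = 1.0
        else:
            scores[names[idx]] = 2.0 * int(np.logical_and(a, b).sum()) / denom
    return ClassScores(scores)
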