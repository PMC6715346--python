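"""Memorability-score machinery.

An image's memorability score in [0, 1] is the predicted chance-corrected
hit rate for recognizing the image as previously seen (0 = chance,
1 = ceiling). This module implements the three pieces of machinery around
such scores:

- the log-linear delay correction relating memorability at one retention
  delay to another,
- the 10-crop preprocessing geometry used to feed images to a
  memorability-predicting network, and
- the clipped linear calibration applied to raw network predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "DecayModel",
    "CalibrationConstants",
    "CROP_ORDER",
    "memorability_at_delay",
    "correct_to_reference",
    "calibrated_score",
    "preprocess_ten_crop",
]

#: Fixed emission order of the ten crops. The mean over crops is
#: order-invariant; the order only matters for serialized fixtures.
CROP_ORDER = (
    "center",
    "top_left",
    "top_right",
    "bottom_left",
    "bottom_right",
    "center_flip",
    "top_left_flip",
    "top_right_flip",
    "bottom_left_flip",
    "bottom_right_flip",
)

_RESIZE_TO = 256
_CROP_SIZE = 227


@dataclass(frozen=True)
class DecayModel:
    """Log-linear memorability decay: m(t) = m(T) + alpha * ln(t / T).

    ``alpha`` is the decay factor (memorability units per log delay;
    negative for forgetting) and ``reference_delay`` is T, in the same
    time units as t. The natural logarithm is used; alpha rescales under
    any other base.
    """

    alpha: float
    reference_delay: float

    def __post_init__(self):
        if not (self.reference_delay > 0):
            raise ValueError("reference_delay T must be positive")
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


def memorability_at_delay(m_T: float, model: DecayModel, t: float) -> float:
    """Memorability after delay ``t`` given the score at the reference delay."""
    if not (t > 0):
        raise ValueError("delay t must be positive")
    return m_T + model.alpha * math.log(t / model.reference_delay)


def correct_to_reference(m_t: float, model: DecayModel, t: float) -> float:
    """Inverse of :func:`memorability_at_delay`: score at the reference delay."""
    if not (t > 0):
        raise ValueError("delay t must be positive")
    return m_t - model.alpha * math.log(t / model.reference_delay)


@dataclass(frozen=True)
class CalibrationConstants:
    """Constants of the clipped linear calibration of raw predictions.

    ``mean_pred`` is the mean raw network prediction over the training
    image set; ``additive_mean`` is the memorability score assigned to an
    image predicted exactly at that mean.
    """

    mean_pred: float = 0.7626
    additive_mean: float = 0.65

    def __post_init__(self):
        if not (math.isfinite(self.mean_pred) and math.isfinite(self.additive_mean)):
            raise ValueError("calibration constants must be finite")


def calibrated_score(
    raw_outputs: Sequence[float],
    constants: CalibrationConstants = CalibrationConstants(),
) -> float:
    """Calibrated memorability score from the ten per-crop raw predictions.

    Averages the ten raw predictions, applies the linear transform
    ``(output - mean_pred) * 2 + additive_mean`` and clips to [0, 1].
    """
    raw = np.asarray(raw_outputs, dtype=float)
    if raw.shape != (10,):
        raise ValueError(f"expected exactly 10 raw predictions, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw predictions must be finite")
    output = float(raw.mean())
    score = (output - constants.mean_pred) * 2.0 + constants.additive_mean
    return min(max(score, 0.0), 1.0)


def _as_rgb_array(image) -> np.ndarray:
    if isinstance(image, Image.Image):
        if image.mode != "RGB":
            raise ValueError(f"expected an RGB image, got mode {image.mode!r}")
        return np.asarray(image)
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) array, got shape {arr.shape}")
    return arr


def preprocess_ten_crop(image, mean_rgb: Sequence[float]) -> np.ndarray:
    """Resize, mean-subtract and extract the ten 227x227 crops.

    The image is resized to 256x256 with bilinear interpolation
    (half-pixel-center convention, as implemented by Pillow), the
    per-channel mean RGB intensity is subtracted, and the center plus
    four corner crops of 227x227 are taken, each also flipped about the
    vertical axis, in the order of :data:`CROP_ORDER`.

    Returns an array of shape (10, 227, 227, 3), float64.
    """
    arr = _as_rgb_array(image)
    mean = np.asarray(mean_rgb, dtype=float)
    if mean.shape != (3,):
        raise ValueError("mean_rgb must be a per-channel triple")

    pil = Image.fromarray(np.ascontiguousarray(arr.astype(np.uint8)))
    if pil.size != (_RESIZE_TO, _RESIZE_TO):
        pil = pil.resize((_RESIZE_TO, _RESIZE_TO), Image.BILINEAR)
    x = np.asarray(pil, dtype=float) - mean[None, None, :]

    c = _CROP_SIZE
    off = (_RESIZE_TO - c) // 2  # center offset, 14 px
    end = _RESIZE_TO - c  # corner offset of the far corners, 29 px
    windows = {
        "center": x[off : off + c, off : off + c],
        "top_left": x[:c, :c],
        "top_right": x[:c, end:],
        "bottom_left": x[end:, :c],
        "bottom_right": x[end:, end:],
    }
    crops = []
    for name in CROP_ORDER:
        base = windows[name.removesuffix("_flip")]
        crops.append(base[:, ::-1, :] if name.endswith("_flip") else base)
    return np.stack(crops, axis=0)
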