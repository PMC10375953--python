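"""CT-style intensity normalization, ROI restriction, and augmentation.

Raw CT intensities in Hounsfield units are clipped to a window (default
[-1000, 250], covering aerated lung through soft tissue) and mapped linearly
to [0, 1]. Pixels outside the organ ROI are zeroed in the image and set to the
ignore label in the mask, so losses and metrics never see them. Stochastic
augmentation (additive Gaussian noise, flips, small rotations and shifts)
applies the identical geometric transform to image, label and ROI, with
nearest-neighbour interpolation for the discrete masks.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Set, Tuple

import numpy as np
from scipy import ndimage

from .records import IGNORE_LABEL, SegmentationRecord

DEFAULT_HU_WINDOW = (-1000.0, 250.0)


@dataclass
class PreprocessConfig:
    hu_window: Tuple[float, float] = DEFAULT_HU_WINDOW
    augmentations: Set[str] = field(
        default_factory=lambda: {"noise", "flip", "rotation", "shift"})
    noise_sd: float = 0.03
    max_rotation_deg: float = 15.0
    max_shift_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.hu_window
        if not low < high:
            raise ValueError(f"hu_window must satisfy low < high, got {self.hu_window}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.augmentations) - {"noise", "flip", "rotation", "shift"}
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")


def hu_window_normalize(raw: np.ndarray,
                        config: Optional[PreprocessConfig] = None) -> np.ndarray:
    """clamp((v - low) / (high - low), 0, 1); monotone non-decreasing in v."""
    config = config or PreprocessConfig()
    raw = np.asarray(raw, dtype=np.float64)
    if np.isnan(raw).any():
        raise ValueError("HU input contains NaN")
    low, high = config.hu_window
    return np.clip((raw - low) / (high - low), 0.0, 1.0)


def hu_inverse(normalized: np.ndarray,
               config: Optional[PreprocessConfig] = None) -> np.ndarray:
    """Map [0, 1] intensities back onto the HU window (synthetic data is
    generated directly in [0, 1]; this exercises the HU path in tests)."""
    config = config or PreprocessConfig()
    low, high = config.hu_window
    return np.asarray(normalized, dtype=np.float64) * (high - low) + low


def apply_roi(image: np.ndarray, label: Optional[np.ndarray],
              roi_mask: np.ndarray, image_id: str = "unnamed"
              ) -> SegmentationRecord:
    """Zero the image and set the label to the ignore value outside the ROI."""
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if image.shape != roi_mask.shape or (
            label is not None and np.asarray(label).shape != image.shape):
        raise ValueError("image/label/roi shapes do not match")
    masked_image = np.where(roi_mask, image, 0.0)
    masked_label = None
    if label is not None:
        masked_label = np.where(roi_mask, label, IGNORE_LABEL).astype(np.uint8)
    return SegmentationRecord(image_id=image_id, image=masked_image,
                              label=masked_label, roi=roi_mask)


def _geometric(arr: np.ndarray, flip_h: bool, flip_v: bool, angle: float,
               shift: Tuple[int, int], order: int, cval: float) -> np.ndarray:
    out = arr
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=order,
                             mode="constant", cval=cval)
    if shift != (0, 0):
        out = ndimage.shift(out, shift, order=order, mode="constant", cval=cval)
    return out


def augment(record: SegmentationRecord, config: PreprocessConfig,
            rng: np.random.Generator) -> SegmentationRecord:
    """One stochastic augmentation draw; identical geometry for image, label
    and ROI, additive noise on the image only. Deterministic given ``rng``."""
    aug = config.augmentations
    flip_h = "flip" in aug and bool(rng.random() < 0.5)
    flip_v = "flip" in aug and bool(rng.random() < 0.5)
    angle = float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)) \
        if "rotation" in aug else 0.0
    shift = (int(rng.integers(-config.max_shift_px, config.max_shift_px + 1)),
             int(rng.integers(-config.max_shift_px, config.max_shift_px + 1))) \
        if "shift" in aug else (0, 0)

    image = _geometric(record.image.astype(np.float64), flip_h, flip_v, angle,
                       shift, order=1, cval=0.0)
    if "noise" in aug and config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    label = record.label
    if label is not None:
        label = _geometric(label.astype(np.float64), flip_h, flip_v, angle,
                           shift, order=0, cval=IGNORE_LABEL).astype(np.uint8)
    roi = record.roi
    if roi is not None:
        roi = _geometric(roi.astype(np.float64), flip_h, flip_v, angle,
                         shift, order=0, cval=0.0).astype(bool)
    return replace(record, image=image.astype(np.float32), label=label, roi=roi)
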