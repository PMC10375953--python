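"""Core record types shared across the pipeline.

A :class:`SegmentationRecord` is one 2-D slice together with its (optional)
dense label mask, (optional) region-of-interest mask, and provenance: whether
the label was drawn by a human annotator or admitted as a pseudo-label during
a self-training round.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Reserved label value for pixels that carry no class (outside the ROI, or
#: on slices without annotations). Excluded from every loss and metric.
IGNORE_LABEL = 255


@dataclass
class SegmentationRecord:
    image_id: str
    image: np.ndarray                    # (H, W) float in [0, 1]
    label: Optional[np.ndarray] = None   # (H, W) int, IGNORE_LABEL outside ROI
    roi: Optional[np.ndarray] = None     # (H, W) bool
    provenance: str = "human"            # "human" | "pseudo" | "none"
    round_admitted: Optional[int] = None
    volume_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.image.shape}")
        if self.label is not None:
            self.label = np.asarray(self.label)
            if self.label.shape != self.image.shape:
                raise ValueError(
                    f"label shape {self.label.shape} != image shape {self.image.shape}"
                )
        if self.roi is not None:
            self.roi = np.asarray(self.roi).astype(bool)
            if self.roi.shape != self.image.shape:
                raise ValueError(
                    f"roi shape {self.roi.shape} != image shape {self.image.shape}"
                )

    def with_label(self, label: np.ndarray, provenance: str,
                   round_admitted: Optional[int] = None) -> "SegmentationRecord":
        return replace(self, label=label, provenance=provenance,
                       round_admitted=round_admitted)


@dataclass
class DatasetState:
    """The evolving partition of training slices.

    ``labeled`` holds every record trained with a dense mask: the original
    human-annotated slices plus any pseudo-labeled slices admitted by
    selective re-training (``provenance == "pseudo"``). ``unlabeled`` holds
    the remaining pool. ``val`` / ``test`` are quarantined at volume level and
    never scored, selected or trained on. ``admission_log`` records
    (round, image_id) for every admission.
    """
    labeled: list = field(default_factory=list)
    unlabeled: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)
    admission_log: list = field(default_factory=list)

    @property
    def pseudo_labeled(self) -> list:
        return [r for r in self.labeled if r.provenance == "pseudo"]

    @property
    def human_labeled(self) -> list:
        return [r for r in self.labeled if r.provenance == "human"]

    def ids(self, which: str) -> set:
        return {r.image_id for r in getattr(self, which)}

    def check_disjoint(self) -> None:
        lab, unlab = self.ids("labeled"), self.ids("unlabeled")
        if lab & unlab:
            raise ValueError(f"labeled/unlabeled overlap: {sorted(lab & unlab)[:5]}")
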