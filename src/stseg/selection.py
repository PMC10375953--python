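"""Stability scoring of pseudo-labels and selective dataset expansion.

During a training round, Q snapshots of the teacher are saved. For an
unlabeled image, each checkpoint predicts a pseudo mask; the stability score

    s_i = sum_{j=1}^{Q-1} meanIOU(Y_ij, Y_iQ)

sums the mean intersection-over-union of each earlier checkpoint's mask
against the final checkpoint's mask. Images whose pseudo masks were stable
throughout training score close to Q-1 and are trusted; the top fraction
(default 25%) of the current unlabeled pool is admitted to the labeled set,
carrying the final checkpoint's mask as its label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import network as N
from .records import IGNORE_LABEL, DatasetState, SegmentationRecord


@dataclass
class CheckpointEnsemble:
    """Ordered teacher snapshots; the last is the round's final teacher."""
    config: N.NetworkConfig
    checkpoints: List[Dict[str, np.ndarray]]
    provenance: List[Tuple[int, int]] = field(default_factory=list)  # (round, step)

    def __post_init__(self) -> None:
        if len(self.checkpoints) < 2:
            raise ValueError("ensemble needs Q >= 2 checkpoints")

    @property
    def q(self) -> int:
        return len(self.checkpoints)

    def models(self) -> List[N.Model]:
        return [N.from_snapshot(self.config, s) for s in self.checkpoints]


@dataclass
class StabilityScore:
    image_id: str
    s_i: float
    pseudo_mask: np.ndarray     # final-checkpoint argmax mask, ROI-restricted


def mean_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mean over classes present in either mask of per-class IoU; pixels that
    are ignore in either mask are excluded."""
    a, b = np.asarray(mask_a), np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    valid = (a != IGNORE_LABEL) & (b != IGNORE_LABEL)
    if not valid.any():
        raise ValueError("mean_iou: both masks entirely ignore")
    av, bv = a[valid], b[valid]
    classes = np.union1d(np.unique(av), np.unique(bv))
    ious = []
    for c in classes:
        in_a, in_b = av == c, bv == c
        union = np.count_nonzero(in_a | in_b)
        inter = np.count_nonzero(in_a & in_b)
        ious.append(inter / union)
    return float(np.mean(ious))


def predict_mask(model: N.Model, image: np.ndarray,
                 roi: Optional[np.ndarray] = None) -> np.ndarray:
    """Unperturbed inference -> argmax class mask, ignore outside the ROI."""
    probs = N.forward(model, image[None])
    mask = probs.argmax(axis=1)[0].astype(np.uint8)
    if roi is not None:
        mask = np.where(np.asarray(roi, bool), mask, IGNORE_LABEL).astype(np.uint8)
    return mask


def stability_score(record: SegmentationRecord,
                    ensemble: CheckpointEnsemble,
                    models: Optional[Sequence[N.Model]] = None) -> StabilityScore:
    """Predict with all Q checkpoints (no perturbations) and sum the mean IoU
    of the first Q-1 masks against the final one. ``models`` lets a caller
    materialize the ensemble once when scoring many images."""
    models = list(models) if models is not None else ensemble.models()
    if len(models) != ensemble.q:
        raise ValueError("missing checkpoint models")
    masks = [predict_mask(m, record.image, record.roi) for m in models]
    final = masks[-1]
    s = sum(mean_iou(m, final) for m in masks[:-1])
    return StabilityScore(image_id=record.image_id, s_i=float(s),
                          pseudo_mask=final)


def score_pool(records: Sequence[SegmentationRecord],
               ensemble: CheckpointEnsemble) -> List[StabilityScore]:
    models = ensemble.models()
    return [stability_score(r, ensemble, models=models) for r in records]


def rank_and_select(scores: Sequence[StabilityScore],
                    fraction: float) -> List[str]:
    """The floor(fraction * N) (at least 1) highest-scored image ids, sorted in
    descending score order; ties broken by ascending image_id."""
    if not scores:
        raise ValueError("rank_and_select: empty score list")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = max(1, int(np.floor(fraction * len(scores))))
    ordered = sorted(scores, key=lambda s: (-s.s_i, s.image_id))
    return [s.image_id for s in ordered[:k]]


def update_datasets(state: DatasetState, selected: Sequence[str],
                    pseudo_masks: Dict[str, np.ndarray],
                    round_index: int = 0) -> DatasetState:
    """Move the selected unlabeled records into the labeled set, carrying
    their pseudo masks and a pseudo-provenance tag. |D_l| + |D_u| is
    conserved; human labels are never overwritten."""
    by_id = {r.image_id: r for r in state.unlabeled}
    labeled_ids = state.ids("labeled")
    for image_id in selected:
        if image_id in labeled_ids:
            raise ValueError(f"{image_id!r} is already in the labeled set")
        if image_id not in by_id:
            raise ValueError(f"{image_id!r} is not in the unlabeled pool")
    selected_set = set(selected)
    moved = [
        by_id[i].with_label(pseudo_masks[i], provenance="pseudo",
                            round_admitted=round_index)
        for i in selected]
    new_state = DatasetState(
        labeled=state.labeled + moved,
        unlabeled=[r for r in state.unlabeled if r.image_id not in selected_set],
        val=state.val, test=state.test,
        admission_log=state.admission_log + [(round_index, i) for i in selected])
    new_state.check_disjoint()
    return new_state
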