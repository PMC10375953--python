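"""Dice evaluation and reporting.

The principal metric is the per-class dice coefficient

    Dice = 2 |X ∩ Y| / (|X| + |Y|)

between the teacher's argmax mask and the reference mask, computed per image
and per class, then aggregated as mean ± sd across the images of a split; the
``Avg`` column is the mean over the per-class means. The teacher (not the
student) is always the evaluated model.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import network as N
from .records import IGNORE_LABEL, SegmentationRecord
from .selection import predict_mask


@dataclass
class DiceReport:
    per_class_mean: Dict[int, float]
    per_class_sd: Dict[int, float]
    average: float
    n_images: int
    round_index: Optional[int] = None
    config_fingerprint: Optional[str] = None

    def to_markdown(self, class_names: Optional[Sequence[str]] = None) -> str:
        classes = sorted(self.per_class_mean)
        names = class_names or [f"C{c}" for c in classes]
        header = "| " + " | ".join(list(names) + ["Avg"]) + " |"
        rule = "|" + "---|" * (len(classes) + 1)
        cells = [f"{100 * self.per_class_mean[c]:.2f} ± "
                 f"{100 * self.per_class_sd[c]:.2f}" for c in classes]
        cells.append(f"{100 * self.average:.2f}")
        return "\n".join([header, rule, "| " + " | ".join(cells) + " |"])

    def to_dict(self) -> dict:
        return {
            "per_class_mean": {int(k): v for k, v in self.per_class_mean.items()},
            "per_class_sd": {int(k): v for k, v in self.per_class_sd.items()},
            "average": self.average, "n_images": self.n_images,
            "round_index": self.round_index,
        }


def dice_coefficient(pred_mask: np.ndarray, truth: np.ndarray,
                     class_id: int) -> Optional[float]:
    """2|X∩Y|/(|X|+|Y|) for one class; ignore pixels excluded. Returns None
    (skipped) when the class is absent from both masks."""
    pred_mask, truth = np.asarray(pred_mask), np.asarray(truth)
    if pred_mask.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {truth.shape}")
    valid = (pred_mask != IGNORE_LABEL) & (truth != IGNORE_LABEL)
    x = (pred_mask == class_id) & valid
    y = (truth == class_id) & valid
    total = np.count_nonzero(x) + np.count_nonzero(y)
    if total == 0:
        return None
    return 2.0 * np.count_nonzero(x & y) / total


def evaluate_split(model: N.Model, records: Sequence[SegmentationRecord],
                   n_classes: int, round_index: Optional[int] = None
                   ) -> DiceReport:
    """Unperturbed inference over a split; per-class dice per image, then
    mean ± sd across images. Classes absent from an image (in both prediction
    and truth) are skipped for that image."""
    records = [r for r in records if r.label is not None]
    if not records:
        raise ValueError("evaluate_split: no labeled records")
    per_class: Dict[int, List[float]] = {c: [] for c in range(n_classes)}
    for rec in records:
        pred = predict_mask(model, rec.image, rec.roi)
        for c in range(n_classes):
            d = dice_coefficient(pred, rec.label, c)
            if d is not None:
                per_class[c].append(d)
    means = {c: float(np.mean(v)) for c, v in per_class.items() if v}
    sds = {c: float(np.std(v)) for c, v in per_class.items() if v}
    average = float(np.mean(list(means.values())))
    return DiceReport(per_class_mean=means, per_class_sd=sds, average=average,
                      n_images=len(records), round_index=round_index)


def ablation_unlabeled_fraction(config, dataset, fractions: Sequence[float],
                                seed: int = 0) -> Dict[float, DiceReport]:
    """Re-run the pipeline with the unlabeled pool subsampled at each fraction
    (seeded); fraction 0 is the supervised-only baseline. Returns one test
    report per fraction. Improvement with fraction is reported as a trend,
    never asserted: individual runs are stochastic."""
    from . import orchestrator as orch  # deferred: circular at import time

    results: Dict[float, DiceReport] = {}
    for frac in fractions:
        sub = orch.subsample_unlabeled(dataset, frac, seed=seed)
        if frac == 0:
            rounds = orch.run_supervised_baseline(sub, config)
        else:
            rounds = orch.run_pipeline(sub, config)
        final_model = N.from_snapshot(config.network,
                                      rounds[-1].ensemble.checkpoints[-1])
        results[frac] = evaluate_split(final_model, dataset.test,
                                       config.network.n_classes)
    return results
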