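"""Seeded synthetic multi-class texture volumes with sparse slice annotations.

The generator emulates the study conditions of sparsely annotated CT-style
volumes: each volume is a stack of correlated 2-D slices in which an
organ-like ROI (two ellipse-like blobs) contains several textured class
regions. A small number of evenly spaced slices are "labeled" (they carry a
dense mask); the +/- ``neighbour_window`` neighbours of each labeled slice
form the unlabeled pool, mirroring the regime where radiologists densely
annotate a few slices and the adjacent, highly correlated slices are left
unlabeled.

Class regions are the argmax of per-class smooth random fields; from slice to
slice the fields are warped by a small random elastic displacement so adjacent
slices are strongly correlated without modelling anatomy. Each class renders
as a base intensity plus a zero-mean structured texture (speckle, cell
lattices, oriented striations, blob clusters) plus i.i.d. Gaussian noise, so
classes are visually separable yet overlapping in intensity.

Everything is bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .records import IGNORE_LABEL, DatasetState, SegmentationRecord

TEXTURE_KINDS = ("smooth", "speckle", "honeycomb", "linear", "blobs")


@dataclass
class TextureClassSpec:
    class_id: int
    base_intensity: float
    texture_kind: str
    noise_sd: float = 0.03
    scale: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_intensity <= 1.0:
            raise ValueError("base_intensity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(
                f"unknown texture_kind {self.texture_kind!r}; "
                f"choose from {TEXTURE_KINDS}")


@dataclass
class SyntheticVolume:
    slices: np.ndarray                  # (S, H, W) float32 in [0, 1]
    dense_labels: np.ndarray            # (S, H, W) uint8, IGNORE_LABEL outside ROI
    roi_masks: np.ndarray               # (S, H, W) bool
    labeled_slice_indices: List[int]
    unlabeled_slice_indices: List[int]
    seed: int
    volume_id: str = "vol"

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def default_specs(n_classes: int = 4) -> List[TextureClassSpec]:
    """The shipped benchmark classes: 4 by default (fast CPU tests), 8 for the
    full texture-pattern mode."""
    full = [
        TextureClassSpec(0, 0.30, "smooth", noise_sd=0.03, scale=8),
        TextureClassSpec(1, 0.55, "speckle", noise_sd=0.04, scale=3),
        TextureClassSpec(2, 0.45, "honeycomb", noise_sd=0.03, scale=7),
        TextureClassSpec(3, 0.70, "blobs", noise_sd=0.04, scale=6),
        TextureClassSpec(4, 0.62, "linear", noise_sd=0.03, scale=5),
        TextureClassSpec(5, 0.38, "honeycomb", noise_sd=0.04, scale=11),
        TextureClassSpec(6, 0.25, "speckle", noise_sd=0.03, scale=2),
        TextureClassSpec(7, 0.50, "blobs", noise_sd=0.04, scale=10),
    ]
    if not 2 <= n_classes <= len(full):
        raise ValueError(f"n_classes must be in [2, {len(full)}]")
    return full[:n_classes]


def _labeled_indices(n_slices: int, n_labeled: int) -> List[int]:
    """Evenly spaced slice indices (segment midpoints)."""
    return [int((i + 0.5) * n_slices / n_labeled) for i in range(n_labeled)]


def _roi_mask(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Two ellipse-like blobs with wobbled boundaries (lung-like ROI)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    mask = np.zeros(shape, bool)
    for cx_frac in (0.28, 0.72):
        cy = 0.5 * h * (1 + rng.uniform(-0.05, 0.05))
        cx = cx_frac * w * (1 + rng.uniform(-0.04, 0.04))
        ay = 0.38 * h * (1 + rng.uniform(-0.08, 0.08))
        ax = 0.18 * w * (1 + rng.uniform(-0.08, 0.08))
        wobble = ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma=h / 8)
        wobble /= max(np.abs(wobble).max(), 1e-9)
        r = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        mask |= r + 0.25 * wobble < 1.0
    return mask


def _class_fields(n_classes: int, shape: Tuple[int, int],
                  rng: np.random.Generator) -> np.ndarray:
    sigma = max(shape) / 7.0
    fields = np.stack([
        ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma=sigma)
        for _ in range(n_classes)])
    # normalize each field so no class dominates by chance
    fields -= fields.mean(axis=(1, 2), keepdims=True)
    fields /= fields.std(axis=(1, 2), keepdims=True) + 1e-12
    return fields


def _warp_fields(fields: np.ndarray, rng: np.random.Generator,
                 amplitude: float = 1.5) -> np.ndarray:
    """Small random elastic displacement shared by all class fields, so region
    boundaries drift smoothly from one slice to the next."""
    _, h, w = fields.shape
    sigma = max(h, w) / 6.0
    dy = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma)
    dx = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma)
    for d in (dy, dx):
        d *= amplitude / (np.abs(d).max() + 1e-12)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + dy, xx + dx])
    return np.stack([
        ndimage.map_coordinates(f, coords, order=1, mode="reflect")
        for f in fields])


def _structured_pattern(spec: TextureClassSpec, shape: Tuple[int, int],
                        rng: np.random.Generator) -> np.ndarray:
    """A fixed per-volume, zero-mean texture pattern for one class."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    kind, s = spec.texture_kind, spec.scale
    if kind == "smooth":
        pat = ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma=s)
        pat /= pat.std() + 1e-12
        pat *= 0.04
    elif kind == "speckle":
        pat = ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma=s / 3.0)
        pat /= pat.std() + 1e-12
        pat *= 0.09
    elif kind == "honeycomb":
        phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
        cells = np.cos(2 * np.pi * yy / s + phase_y) * \
            np.cos(2 * np.pi * xx / s + phase_x)
        pat = 0.11 * cells
    elif kind == "linear":
        theta = rng.uniform(0, np.pi)
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        pat = 0.10 * np.sin(2 * np.pi * proj / s + rng.uniform(0, 2 * np.pi))
    elif kind == "blobs":
        f = ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma=s / 2.0)
        pat = 0.10 * np.where(f > f.std() * 0.5, 1.0, -0.4)
    else:  # pragma: no cover - guarded by TextureClassSpec
        raise ValueError(kind)
    return pat - pat.mean()


def generate_volume(specs: Sequence[TextureClassSpec], n_slices: int,
                    shape: Tuple[int, int], n_labeled: int,
                    neighbour_window: int, seed: int,
                    volume_id: str = "vol") -> SyntheticVolume:
    """Generate one synthetic volume; deterministic for a fixed seed."""
    if not specs:
        raise ValueError("specs must be non-empty")
    ids = [s.class_id for s in specs]
    if sorted(ids) != list(range(len(specs))):
        raise ValueError("class_ids must be unique and contiguous from 0")
    if n_labeled < 1:
        raise ValueError("n_labeled must be >= 1")
    if n_labeled * (2 * neighbour_window + 1) > n_slices:
        raise ValueError(
            f"infeasible geometry: {n_labeled} labeled slices with window "
            f"+/-{neighbour_window} need >= {n_labeled * (2 * neighbour_window + 1)} "
            f"slices, volume has {n_slices}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    n_classes = len(specs)
    roi = _roi_mask(shape, rng)
    fields = _class_fields(n_classes, shape, rng)
    patterns = [_structured_pattern(sp, shape, rng) for sp in specs]
    order = np.argsort(ids)

    slices = np.empty((n_slices,) + tuple(shape), dtype=np.float32)
    labels = np.full((n_slices,) + tuple(shape), IGNORE_LABEL, dtype=np.uint8)
    rois = np.repeat(roi[None], n_slices, axis=0)

    for s in range(n_slices):
        if s > 0:
            fields = _warp_fields(fields, rng)
        lab = np.argmax(fields, axis=0).astype(np.uint8)
        img = np.zeros(shape, dtype=np.float64)
        for k in order:
            sp = specs[k]
            region = lab == sp.class_id
            centering = region & roi if (region & roi).any() else region
            if not region.any():
                continue
            # center the structured texture within the visible (ROI) part of
            # the region so the regional mean intensity equals the base level
            struct = patterns[k] - patterns[k][centering].mean()
            tex = sp.base_intensity + struct + \
                rng.normal(0, sp.noise_sd, size=shape)
            img[region] = tex[region]
        img[~roi] = 0.0
        slices[s] = np.clip(img, 0.0, 1.0)
        lab_masked = np.where(roi, lab, IGNORE_LABEL).astype(np.uint8)
        labels[s] = lab_masked

    labeled_idx = _labeled_indices(n_slices, n_labeled)
    pool = sorted({
        j for i in labeled_idx
        for j in range(i - neighbour_window, i + neighbour_window + 1)
        if 0 <= j < n_slices and j not in labeled_idx})
    return SyntheticVolume(slices=slices, dense_labels=labels, roi_masks=rois,
                           labeled_slice_indices=labeled_idx,
                           unlabeled_slice_indices=pool, seed=seed,
                           volume_id=volume_id)


def volume_records(volume: SyntheticVolume, labeled_only: bool = False,
                   strip_unlabeled_masks: bool = True) -> List[SegmentationRecord]:
    """Expand a volume into per-slice records. Labeled slices carry their
    dense mask (human provenance); pool slices carry no label unless
    ``strip_unlabeled_masks`` is False (analysis use only)."""
    recs = []
    for idx in volume.labeled_slice_indices:
        recs.append(SegmentationRecord(
            image_id=f"{volume.volume_id}_s{idx:03d}",
            image=volume.slices[idx], label=volume.dense_labels[idx],
            roi=volume.roi_masks[idx], provenance="human",
            volume_id=volume.volume_id))
    if labeled_only:
        return recs
    for idx in volume.unlabeled_slice_indices:
        recs.append(SegmentationRecord(
            image_id=f"{volume.volume_id}_s{idx:03d}",
            image=volume.slices[idx],
            label=None if strip_unlabeled_masks else volume.dense_labels[idx],
            roi=volume.roi_masks[idx], provenance="none",
            volume_id=volume.volume_id))
    return recs


def make_split(volumes: Sequence[SyntheticVolume],
               ratios: Tuple[float, float, float] = (0.7, 0.15, 0.15)
               ) -> DatasetState:
    """Partition at volume granularity (never by slice) into train/val/test;
    the train portion is split into labeled slices and the unlabeled pool."""
    if len(volumes) < 3:
        raise ValueError(f"need >= 3 volumes, got {len(volumes)}")
    if any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be nonnegative with positive sum")
    n = len(volumes)
    n_val = max(1, int(round(ratios[1] / sum(ratios) * n)))
    n_test = max(1, int(round(ratios[2] / sum(ratios) * n)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("split leaves no training volumes")
    train, val, test = (volumes[:n_train], volumes[n_train:n_train + n_val],
                        volumes[n_train + n_val:])
    state = DatasetState()
    for v in train:
        recs = volume_records(v)
        state.labeled.extend(r for r in recs if r.provenance == "human")
        state.unlabeled.extend(r for r in recs if r.provenance == "none")
    for v in val:
        state.val.extend(volume_records(v, labeled_only=True))
    for v in test:
        state.test.extend(volume_records(v, labeled_only=True))
    state.check_disjoint()
    return state


def default_benchmark(seed: int, n_volumes: int = 12, n_slices: int = 21,
                      shape: Tuple[int, int] = (64, 64), n_labeled: int = 3,
                      neighbour_window: int = 3, n_classes: int = 4
                      ) -> Tuple[List[SyntheticVolume], DatasetState]:
    """The shipped benchmark: 12 volumes (8 train / 2 val / 2 test),
    21 slices of 64x64, 3 labeled slices per volume with a +/-3 unlabeled
    neighbourhood -> 24 labeled + 144 unlabeled training slices."""
    specs = default_specs(n_classes)
    root = np.random.SeedSequence([int(seed), 0xBE7C])
    vol_seeds = root.generate_state(n_volumes) % (2 ** 31)
    volumes = [
        generate_volume(specs, n_slices, shape, n_labeled, neighbour_window,
                        seed=int(vs), volume_id=f"case{i:03d}")
        for i, vs in enumerate(vol_seeds)]
    return volumes, make_split(volumes, ratios=(8 / 12, 2 / 12, 2 / 12))
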