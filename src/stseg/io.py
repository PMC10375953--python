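"""Readers and writers: volumes, masks, manifests, configs, checkpoints.

Supported case formats:

* ``nifti`` — one ``.nii.gz`` per component (image / labels / roi), slices
  along the last axis;
* ``png``   — one 8-bit grayscale PNG per image slice plus paletted mask PNGs;
* ``npz``   — a single NumPy archive per case.

A JSON manifest lists the cases, their file paths, labeled slice indices and
split membership. Masks use contiguous class ids from 0 with 255 as the
ignore value; slice indices are 0-based. Image intensities already in [0, 1]
are passed through; HU-valued inputs (detected by value range or an explicit
manifest flag) are routed through the HU window normalization.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from . import network as N
from .preprocessing import PreprocessConfig, hu_window_normalize
from .records import IGNORE_LABEL
from .synthetic import SyntheticVolume

# a fixed distinguishable palette for up to 8 classes + ignore
_PALETTE = [
    (0, 0, 0), (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240),
]


def _mask_png(mask: np.ndarray) -> Image.Image:
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for c in range(256):
        palette.extend(_PALETTE[c] if c < len(_PALETTE) else (40, 40, 40))
    palette[IGNORE_LABEL * 3:IGNORE_LABEL * 3 + 3] = (255, 255, 255)
    img.putpalette(palette)
    return img


def write_case(volume: SyntheticVolume, out_dir: Path, fmt: str = "nifti") -> dict:
    """Write one case; returns its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cid = volume.volume_id
    entry = {
        "case_id": cid, "format": fmt, "normalized": True,
        "labeled_slice_indices": list(map(int, volume.labeled_slice_indices)),
        "unlabeled_slice_indices": list(map(int, volume.unlabeled_slice_indices)),
        "seed": int(volume.seed),
    }
    if fmt == "nifti":
        for name, arr, dtype in (("image", volume.slices, np.float32),
                                 ("labels", volume.dense_labels, np.uint8),
                                 ("roi", volume.roi_masks.astype(np.uint8), np.uint8)):
            path = out_dir / f"{cid}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(
                np.transpose(arr, (1, 2, 0)).astype(dtype), np.eye(4)), path)
            entry[name] = path.name
    elif fmt == "png":
        case_dir = out_dir / cid
        case_dir.mkdir(exist_ok=True)
        for s in range(volume.n_slices):
            Image.fromarray(
                np.round(volume.slices[s] * 255).astype(np.uint8), mode="L"
            ).save(case_dir / f"slice{s:03d}.png")
            _mask_png(volume.dense_labels[s]).save(case_dir / f"mask{s:03d}.png")
            _mask_png(volume.roi_masks[s].astype(np.uint8)
                      ).save(case_dir / f"roi{s:03d}.png")
        entry["dir"] = cid
        entry["n_slices"] = int(volume.n_slices)
    elif fmt == "npz":
        path = out_dir / f"{cid}.npz"
        np.savez_compressed(path, slices=volume.slices,
                            dense_labels=volume.dense_labels,
                            roi_masks=volume.roi_masks)
        entry["archive"] = path.name
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return entry


def read_case(entry: dict, root: Path,
              preprocess: Optional[PreprocessConfig] = None) -> SyntheticVolume:
    """Read one manifest entry back into a volume record set."""
    root = Path(root)
    fmt = entry["format"]
    cid = entry["case_id"]
    if fmt == "nifti":
        def load(name):
            return np.transpose(
                np.asarray(nib.load(root / entry[name]).dataobj), (2, 0, 1))
        slices = load("image").astype(np.float64)
        labels = load("labels").astype(np.uint8)
        roi = load("roi").astype(bool)
    elif fmt == "png":
        case_dir = root / entry["dir"]
        n = int(entry["n_slices"])
        slices = np.stack([
            np.asarray(Image.open(case_dir / f"slice{s:03d}.png"),
                       dtype=np.float64) / 255.0 for s in range(n)])
        labels = np.stack([
            np.asarray(Image.open(case_dir / f"mask{s:03d}.png"), dtype=np.uint8)
            for s in range(n)])
        roi = np.stack([
            np.asarray(Image.open(case_dir / f"roi{s:03d}.png"), dtype=np.uint8)
            for s in range(n)]).astype(bool)
    elif fmt == "npz":
        with np.load(root / entry["archive"]) as z:
            slices = z["slices"].astype(np.float64)
            labels = z["dense_labels"].astype(np.uint8)
            roi = z["roi_masks"].astype(bool)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if slices.shape != labels.shape or slices.shape != roi.shape:
        raise ValueError(f"case {cid}: image/mask/roi shapes disagree: "
                         f"{slices.shape}/{labels.shape}/{roi.shape}")
    n_classes = int(labels[labels != IGNORE_LABEL].max(initial=0)) + 1
    if n_classes > 64:
        raise ValueError(f"case {cid}: mask contains out-of-range class ids")
    hu_valued = not entry.get("normalized", slices.min() >= 0 and slices.max() <= 1)
    if hu_valued or slices.min() < -0.01 or slices.max() > 1.01:
        slices = hu_window_normalize(slices, preprocess)
    labeled_idx = [int(i) for i in entry["labeled_slice_indices"]]
    if labeled_idx and (min(labeled_idx) < 0 or max(labeled_idx) >= len(slices)):
        raise ValueError(f"case {cid}: labeled slice index out of range")
    return SyntheticVolume(
        slices=slices.astype(np.float32), dense_labels=labels, roi_masks=roi,
        labeled_slice_indices=labeled_idx,
        unlabeled_slice_indices=[int(i) for i in
                                 entry.get("unlabeled_slice_indices", [])],
        seed=int(entry.get("seed", 0)), volume_id=cid)


def write_manifest(entries: List[dict], path: Path, splits: dict) -> None:
    Path(path).write_text(json.dumps(
        {"cases": entries, "splits": splits}, indent=2))


def read_manifest(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def save_checkpoint(path: Path, model: N.Model, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, __config__=json.dumps(dataclasses.asdict(model.config)),
        __meta__=json.dumps(meta or {}), **N.snapshot(model))


def load_checkpoint(path: Path) -> N.Model:
    with np.load(path, allow_pickle=False) as z:
        config = N.NetworkConfig(**json.loads(str(z["__config__"])))
        snap = {k: z[k] for k in z.files if not k.startswith("__")}
    return N.from_snapshot(config, snap)


def load_run_config(path: Path):
    """Build a RunConfig from a YAML file with optional ``network:`` and
    ``preprocess:`` blocks mirroring the dataclass fields."""
    from .orchestrator import RunConfig
    raw = yaml.safe_load(Path(path).read_text()) or {}
    net = N.NetworkConfig(**raw.pop("network", {}))
    raw.pop("preprocess", None)
    return RunConfig(network=net, **raw)
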