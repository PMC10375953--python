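"""Segmentation backbones.

Two variants are provided, both mapping a (B, 1, H, W) normalized image batch
to (B, T, H, W) class scores:

* ``tiny`` — a small two-level encoder/decoder with a skip connection; a few
  thousand parameters, intended for CPU-scale experiments and tests.
* ``multires`` — a miniature parallel multi-resolution network: a
  full-resolution stream is maintained end to end while lower-resolution
  streams run in parallel, and every exchange block fuses information across
  all streams by resize-and-sum. This keeps the two defining properties of
  high-resolution backbones (parallel streams, repeated cross-resolution
  fusion) at a size where desk-scale training is practical.

Dropout (model perturbation) is applied to the last feature map before the
classification head.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import tape as T
from .tape import Node, Param, Tape


@dataclass
class NetworkConfig:
    n_classes: int = 4
    n_streams: int = 2
    base_width: int = 16
    n_exchange_blocks: int = 2
    dropout_rate: float = 0.5
    variant: str = "tiny"          # "tiny" | "multires"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_streams < 1:
            raise ValueError("n_streams must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.variant not in ("tiny", "multires"):
            raise ValueError(f"unknown variant {self.variant!r}")


class Model:
    """A parameter dictionary plus the wiring of one network variant."""

    def __init__(self, config: NetworkConfig, params: Dict[str, Param]):
        self.config = config
        self.params = params

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params.values())

    def forward_logits(self, tp: Tape, x: Node, dropout_on: bool = False,
                       rng: Optional[np.random.Generator] = None) -> Node:
        if dropout_on and self.config.dropout_rate > 0 and rng is None:
            raise ValueError("dropout requires an rng")
        if self.config.variant == "tiny":
            return self._forward_tiny(tp, x, dropout_on, rng)
        return self._forward_multires(tp, x, dropout_on, rng)

    def _forward_tiny(self, tp, x, dropout_on, rng):
        p = self.params
        h1 = T.relu(tp, T.conv2d(tp, x, p["c1_w"], p["c1_b"]))
        h2 = T.relu(tp, T.conv2d(tp, h1, p["c2_w"], p["c2_b"]))
        d = T.avg_pool2(tp, h2)
        h3 = T.relu(tp, T.conv2d(tp, d, p["c3_w"], p["c3_b"]))
        u = T.upsample2(tp, T.conv2d(tp, h3, p["proj_w"], p["proj_b"]))
        f = T.relu(tp, T.add(tp, h2, u))
        f = T.dropout(tp, f, self.config.dropout_rate, rng, dropout_on)
        return T.conv2d(tp, f, p["head_w"], p["head_b"])

    def _forward_multires(self, tp, x, dropout_on, rng):
        p, cfg = self.params, self.config
        _, _, height, width = x.value.shape
        div = 2 ** (cfg.n_streams - 1)
        if height % div or width % div:
            raise ValueError(
                f"input {height}x{width} not divisible by 2^(n_streams-1)={div}")
        feats = [T.relu(tp, T.conv2d(tp, x, p["stem_w"], p["stem_b"]))]
        for s in range(1, cfg.n_streams):
            down = T.avg_pool2(tp, feats[-1])
            feats.append(T.relu(tp, T.conv2d(
                tp, down, p[f"init{s}_w"], p[f"init{s}_b"])))
        for blk in range(cfg.n_exchange_blocks):
            feats = [T.relu(tp, T.conv2d(
                tp, f, p[f"b{blk}s{s}_w"], p[f"b{blk}s{s}_b"]))
                for s, f in enumerate(feats)]
            if cfg.n_streams > 1:
                fused = []
                for dst in range(cfg.n_streams):
                    acc = feats[dst]
                    for src in range(cfg.n_streams):
                        if src == dst:
                            continue
                        g = T.conv2d(tp, feats[src],
                                     p[f"x{blk}_{src}to{dst}_w"],
                                     p[f"x{blk}_{src}to{dst}_b"])
                        if src < dst:
                            for _ in range(dst - src):
                                g = T.avg_pool2(tp, g)
                        else:
                            for _ in range(src - dst):
                                g = T.upsample2(tp, g)
                        acc = T.add(tp, acc, g)
                    fused.append(T.relu(tp, acc))
                feats = fused
        f = T.dropout(tp, feats[0], cfg.dropout_rate, rng, dropout_on)
        return T.conv2d(tp, f, p["head_w"], p["head_b"])


def _he(rng: np.random.Generator, n_out: int, n_in: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (n_in * k * k))
    return rng.normal(0.0, std, size=(n_out, n_in, k, k)).astype(np.float32)


def _conv_pair(params, name, rng, n_out, n_in, k):
    params[f"{name}_w"] = Param(_he(rng, n_out, n_in, k))
    params[f"{name}_b"] = Param(np.zeros(n_out, dtype=np.float32))


def build(config: NetworkConfig, seed: int) -> Model:
    """Deterministically initialize a model for the given config and seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB111D]))
    params: Dict[str, Param] = {}
    w, t = config.base_width, config.n_classes
    if config.variant == "tiny":
        _conv_pair(params, "c1", rng, w, 1, 3)
        _conv_pair(params, "c2", rng, w, w, 3)
        _conv_pair(params, "c3", rng, 2 * w, w, 3)
        _conv_pair(params, "proj", rng, w, 2 * w, 1)
        _conv_pair(params, "head", rng, t, w, 1)
    else:
        widths = [w * 2 ** s for s in range(config.n_streams)]
        _conv_pair(params, "stem", rng, widths[0], 1, 3)
        for s in range(1, config.n_streams):
            _conv_pair(params, f"init{s}", rng, widths[s], widths[s - 1], 3)
        for blk in range(config.n_exchange_blocks):
            for s in range(config.n_streams):
                _conv_pair(params, f"b{blk}s{s}", rng, widths[s], widths[s], 3)
            if config.n_streams > 1:
                for src in range(config.n_streams):
                    for dst in range(config.n_streams):
                        if src != dst:
                            _conv_pair(params, f"x{blk}_{src}to{dst}",
                                       rng, widths[dst], widths[src], 1)
        _conv_pair(params, "head", rng, t, widths[0], 1)
    return Model(config, params)


def forward(model: Model, batch: np.ndarray,
            perturb: Optional[dict] = None,
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Inference forward pass: returns softmax probabilities (B, T, H, W).

    ``perturb`` may carry ``dropout_on`` (model perturbation) and ``noise_sd``
    (additive input noise, drawn fresh from ``rng`` per call). With no
    perturbation the forward pass is deterministic.
    """
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.min() < -0.5 or x.max() > 1.5:
        import warnings
        warnings.warn("input does not look normalized to [0, 1]", stacklevel=2)
    perturb = perturb or {}
    noise_sd = float(perturb.get("noise_sd", 0.0))
    dropout_on = bool(perturb.get("dropout_on", False))
    if (noise_sd > 0 or dropout_on) and rng is None:
        raise ValueError("perturbed forward requires an rng")
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape).astype(np.float32)
    tp = Tape()
    logits = model.forward_logits(tp, Node(x), dropout_on, rng)
    return T.softmax(logits.value, axis=1)


def snapshot(model: Model) -> Dict[str, np.ndarray]:
    return {k: p.value.copy() for k, p in model.params.items()}


def from_snapshot(config: NetworkConfig, snap: Dict[str, np.ndarray]) -> Model:
    return Model(copy.deepcopy(config), {k: Param(v.copy()) for k, v in snap.items()})


def clone(model: Model) -> Model:
    return from_snapshot(model.config, snapshot(model))
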