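"""Mean-teacher coupling: EMA weight update and one optimization step.

The student network is trained by gradient descent on

    L_total = L_sup(labeled) + lambda * L_con(teacher, student; all members)

while the teacher is never touched by backpropagation: after every student
step its parameters are updated as an exponential moving average

    theta*_z = alpha * theta*_{z-1} + (1 - alpha) * theta_z

with a smaller alpha (0.99) during the early ramp-up phase of a round and a
larger one (0.999) afterwards, so a young, fast-moving student influences the
teacher quickly while a mature student is averaged over a long horizon.

Teacher and student each receive an independently perturbed view of the same
batch (fresh additive input noise per forward; dropout on the student only).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from . import losses as L
from . import network as N
from .tape import Node, Tape, softmax, softmax_backward


@dataclass
class EMAConfig:
    alpha_rampup: float = 0.99
    alpha_main: float = 0.999
    rampup_steps: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_rampup, self.alpha_main):
            if not 0.0 < a < 1.0 and a not in (0.0, 1.0):
                raise ValueError(f"alpha must be in (0,1), got {a}")


@dataclass
class ModelPair:
    student: N.Model
    teacher: N.Model
    step_counter: int = 0

    def __post_init__(self) -> None:
        if set(self.student.params) != set(self.teacher.params):
            raise ValueError("student/teacher architectures differ")


def make_pair(config: N.NetworkConfig, seed: int) -> ModelPair:
    """Fresh student with the teacher initialized as an exact copy."""
    student = N.build(config, seed)
    return ModelPair(student=student, teacher=N.clone(student))


def current_alpha(step: int, config: EMAConfig) -> float:
    return config.alpha_rampup if step <= config.rampup_steps else config.alpha_main


def ema_update(pair: ModelPair, config: EMAConfig,
               alpha: Optional[float] = None) -> ModelPair:
    """In-place EMA of teacher parameters toward the student; returns the pair."""
    if alpha is None:
        if pair.step_counter < 1:
            raise ValueError("ema_update requires step_counter >= 1")
        alpha = current_alpha(pair.step_counter, config)
    for name, tp in pair.teacher.params.items():
        sp = pair.student.params[name]
        if tp.value.shape != sp.value.shape:
            raise ValueError(f"architecture mismatch at parameter {name!r}")
        tp.value = alpha * tp.value + (1.0 - alpha) * sp.value
    return pair


@dataclass
class OptimizerState:
    """RMSProp: adaptive per-parameter step size, no momentum. Gradients are
    clipped to a global L2 norm first; single-slice batches make raw gradient
    norms heavy-tailed."""
    lr: float = 1e-3
    decay: float = 0.99
    eps: float = 1e-8
    clip_norm: float = 5.0
    ms: Dict[str, np.ndarray] = field(default_factory=dict)


def init_optimizer(model: N.Model, lr: float = 1e-3,
                   clip_norm: float = 5.0) -> OptimizerState:
    state = OptimizerState(lr=lr, clip_norm=clip_norm)
    state.ms = {k: np.zeros_like(p.value) for k, p in model.params.items()}
    return state


def apply_gradients(model: N.Model, state: OptimizerState) -> None:
    if state.clip_norm:
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in model.params.values() if p.grad is not None))
        if total > state.clip_norm:
            scale = state.clip_norm / total
            for p in model.params.values():
                if p.grad is not None:
                    p.grad *= scale
    for name, p in model.params.items():
        if p.grad is None:
            continue
        g = p.grad
        ms = state.ms[name]
        ms *= state.decay
        ms += (1.0 - state.decay) * g * g
        p.value -= (state.lr * g / (np.sqrt(ms) + state.eps)).astype(np.float32)
        p.grad = None


def step_rngs(seed: int, round_index: int, step: int
              ) -> Tuple[np.random.Generator, np.random.Generator]:
    """Independent, reproducible per-step generators for the student and
    teacher views. Keying by (seed, round, step, role) makes every step's
    stochasticity independent of how many draws earlier steps consumed."""
    mk = lambda role: np.random.default_rng(
        np.random.SeedSequence([int(seed), int(round_index), int(step), role]))
    return mk(0), mk(1)


def perturbed_forward(model: N.Model, images: np.ndarray,
                      rng: np.random.Generator, noise_sd: float,
                      dropout_on: bool) -> Tuple[Tape, Node, np.ndarray]:
    """Forward pass with fresh input noise (and optionally dropout), keeping
    the tape so gradients can be propagated. Returns (tape, logits, probs)."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape).astype(np.float32)
    tp = Tape()
    logits = model.forward_logits(tp, Node(x), dropout_on=dropout_on, rng=rng)
    return tp, logits, softmax(logits.value, axis=1)


def _stack(batch: dict, key: str) -> Optional[np.ndarray]:
    v = batch.get(key)
    return None if v is None else np.asarray(v)


def training_step(pair: ModelPair, labeled_batch: dict, unlabeled_batch: dict,
                  loss_config: L.LossConfig, ema_config: EMAConfig,
                  optimizer_state: OptimizerState,
                  rng_student: np.random.Generator,
                  rng_teacher: np.random.Generator,
                  noise_sd: float = 0.05) -> Dict[str, float]:
    """One total-loss gradient step on the student followed by an EMA update.

    ``labeled_batch``: {"images": (L,H,W), "labels": (L,H,W), "roi": optional}.
    ``unlabeled_batch``: {"images": (U,H,W), "roi": optional}; U may be 0.
    The supervised loss runs on the labeled members only; the consistency loss
    runs on every member, each model seeing its own perturbed view. Returns
    the scalar loss components for logging.
    """
    x_lab = _stack(labeled_batch, "images")
    if x_lab is None or len(x_lab) == 0:
        raise ValueError("training_step requires a non-empty labeled batch")
    y_lab = _stack(labeled_batch, "labels")
    if y_lab is None:
        raise ValueError("labeled batch carries no labels")
    n_lab = len(x_lab)
    x_unl = _stack(unlabeled_batch, "images") if unlabeled_batch else None
    if x_unl is not None and len(x_unl) == 0:
        x_unl = None
    x_all = x_lab if x_unl is None else np.concatenate([x_lab, x_unl], axis=0)

    roi_parts = []
    for batch, x in ((labeled_batch, x_lab),
                     (unlabeled_batch if x_unl is not None else None, x_unl)):
        if batch is None:
            continue
        roi = _stack(batch, "roi")
        roi_parts.append(np.ones(x.shape, bool) if roi is None else roi.astype(bool))
    roi_all = np.concatenate(roi_parts, axis=0)

    tp, logits, p_student = perturbed_forward(
        pair.student, x_all, rng_student, noise_sd, dropout_on=True)
    p_teacher = N.forward(pair.teacher, x_all,
                          perturb={"noise_sd": noise_sd}, rng=rng_teacher)

    l_sup, l_dice, l_focal, g_sup = L.supervised_loss_with_grad(
        p_student[:n_lab], y_lab, loss_config)
    lam = L.lambda_schedule(pair.step_counter, loss_config)
    l_con, g_con = L.consistency_loss_with_grad(p_teacher, p_student, roi_all)

    dprobs = lam * g_con
    dprobs[:n_lab] += g_sup
    dlogits = softmax_backward(p_student, dprobs, axis=1).astype(np.float32)
    tp.backward(logits, dlogits)
    apply_gradients(pair.student, optimizer_state)

    pair.step_counter += 1
    ema_update(pair, ema_config)
    return {"sup": l_sup, "dice": l_dice, "focal": l_focal,
            "con": l_con, "lambda": lam,
            "total": L.total_loss(l_sup, l_con, lam)}
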