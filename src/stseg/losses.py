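"""Loss functions for semi-supervised segmentation training.

The supervised loss is the convex combination

    L_sup = (1 - rho) * L_dice + rho * L_focal

of a soft multi-class dice loss and a focal loss with per-class balancing
weights beta_t and focusing parameter gamma. The consistency term is the mean
squared error between teacher and student class-probability maps, weighted by
a coefficient lambda that ramps up from ~0 to lambda_max over the early steps
of each training round:

    L_total = L_sup + lambda * L_con .

Conventions
-----------
Probability maps are float arrays of shape (T, H, W) or (B, T, H, W) whose
class axis sums to 1 per pixel. Label masks are integer arrays of shape
(H, W) / (B, H, W) with values in {0..T-1} or IGNORE_LABEL (255); ignore
pixels are excluded from every reduction.

Each loss has a ``*_with_grad`` companion returning the analytic gradient with
respect to the probability map, which the trainer chains through the softmax.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .records import IGNORE_LABEL

_EPS_DICE = 1e-6
_CLAMP = 1e-7


@dataclass
class LossConfig:
    """Hyper-parameters of the compound loss.

    rho balances dice vs focal (default 0.75: focal-dominant).
    gamma >= 0 is the focal focusing exponent (default 2).
    beta holds per-class weights; ``None`` means uniform 1.
    focal_true_class_only switches the per-pixel focal sum from all T
    one-vs-rest terms (default, literal reading) to the true-class term only.
    """
    rho: float = 0.75
    gamma: float = 2.0
    beta: Optional[np.ndarray] = None
    lambda_max: float = 1.0
    ramp_length: int = 100
    focal_true_class_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0,1], got {self.rho}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=np.float64)
            if np.any(self.beta <= 0):
                raise ValueError("beta weights must be strictly positive")


def _batched(pred: np.ndarray, truth: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.ndim == 3:
        pred = pred[None]
        truth = truth[None]
    if pred.ndim != 4 or truth.ndim != 3:
        raise ValueError(f"bad shapes: pred {pred.shape}, truth {truth.shape}")
    if pred.shape[0] != truth.shape[0] or pred.shape[2:] != truth.shape[1:]:
        raise ValueError(f"pred {pred.shape} and truth {truth.shape} disagree")
    return pred, truth


def _one_hot(truth: np.ndarray, n_classes: int) -> Tuple[np.ndarray, np.ndarray]:
    """Returns (one_hot (B,T,H,W), valid (B,H,W)); ignore pixels are all-zero."""
    valid = truth != IGNORE_LABEL
    if np.any((truth < 0) | ((truth >= n_classes) & valid)):
        raise ValueError("label mask contains class ids outside {0..T-1} u {ignore}")
    clipped = np.where(valid, truth, 0)
    onehot = np.zeros((truth.shape[0], n_classes) + truth.shape[1:], dtype=np.float64)
    np.put_along_axis(onehot, clipped[:, None], 1.0, axis=1)
    onehot *= valid[:, None]
    return onehot, valid


def dice_loss_with_grad(pred: np.ndarray, truth: np.ndarray
                        ) -> Tuple[float, np.ndarray]:
    """Soft dice loss 1 - (1/T') sum_t 2*sum(p_t y_t)/(sum p_t^2 + sum y_t^2 + eps).

    Reduction is per class over the whole batch; the mean runs over the T'
    classes present in the truth (empty classes are skipped). Ignore pixels
    contribute to neither numerator nor denominator.
    """
    pred, truth = _batched(pred, truth)
    n_classes = pred.shape[1]
    onehot, valid = _one_hot(truth, n_classes)
    if not valid.any():
        raise ValueError("dice_loss: all pixels are ignored")
    vm = valid[:, None]
    p = pred * vm
    inter = (p * onehot).sum(axis=(0, 2, 3))           # A_t
    denom = (p * p).sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + _EPS_DICE
    present = onehot.sum(axis=(0, 2, 3)) > 0
    n_present = int(present.sum())
    if n_present == 0:
        raise ValueError("dice_loss: no class present in truth")
    terms = 2.0 * inter[present] / denom[present]
    loss = 1.0 - terms.mean()

    grad = np.zeros_like(pred)
    sel = np.where(present)[0]
    a = inter[sel][None, :, None, None]
    b = denom[sel][None, :, None, None]
    grad[:, sel] = -(2.0 * onehot[:, sel] * b - 4.0 * a * p[:, sel]) / (b * b)
    grad /= n_present
    grad *= vm
    return float(loss), grad


def dice_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    return dice_loss_with_grad(pred, truth)[0]


def _resolve_beta(config: LossConfig, n_classes: int) -> np.ndarray:
    if config.beta is None:
        return np.ones(n_classes)
    if len(config.beta) != n_classes:
        raise ValueError(
            f"beta has length {len(config.beta)}, expected {n_classes}")
    return config.beta


def focal_loss_with_grad(pred: np.ndarray, truth: np.ndarray, config: LossConfig
                         ) -> Tuple[float, np.ndarray]:
    """Focal loss: mean over valid pixels of sum_t beta_t (1-h_t)^gamma (-log h_t),
    with h_t = p_t when y_t = 1 and 1 - p_t otherwise."""
    pred, truth = _batched(pred, truth)
    n_classes = pred.shape[1]
    beta = _resolve_beta(config, n_classes)[None, :, None, None]
    onehot, valid = _one_hot(truth, n_classes)
    if not valid.any():
        raise ValueError("focal_loss: all pixels are ignored")
    n_valid = int(valid.sum())
    gamma = config.gamma

    h = np.where(onehot > 0, pred, 1.0 - pred)
    h = np.clip(h, _CLAMP, 1.0 - _CLAMP)
    mod = (1.0 - h) ** gamma
    terms = beta * mod * (-np.log(h))
    if config.focal_true_class_only:
        weight = onehot
    else:
        weight = np.ones_like(terms)
    vm = valid[:, None]
    loss = float((terms * weight * vm).sum() / n_valid)

    # d/dh [-beta (1-h)^g log h] = beta*g*(1-h)^(g-1)*log h - beta*(1-h)^g / h
    if gamma > 0:
        dmod = gamma * (1.0 - h) ** (gamma - 1.0)
    else:
        dmod = np.zeros_like(h)
    dterm_dh = beta * (dmod * np.log(h) - mod / h)
    dh_dp = np.where(onehot > 0, 1.0, -1.0)
    grad = dterm_dh * dh_dp * weight * vm / n_valid
    return loss, grad


def focal_loss(pred: np.ndarray, truth: np.ndarray, config: LossConfig) -> float:
    return focal_loss_with_grad(pred, truth, config)[0]


def supervised_loss_with_grad(pred: np.ndarray, truth: np.ndarray,
                              config: LossConfig
                              ) -> Tuple[float, float, float, np.ndarray]:
    """Returns (L_sup, L_dice, L_focal, dL_sup/dpred)."""
    l_dice, g_dice = dice_loss_with_grad(pred, truth)
    l_focal, g_focal = focal_loss_with_grad(pred, truth, config)
    rho = config.rho
    return ((1.0 - rho) * l_dice + rho * l_focal, l_dice, l_focal,
            (1.0 - rho) * g_dice + rho * g_focal)


def supervised_loss(pred: np.ndarray, truth: np.ndarray,
                    config: LossConfig) -> float:
    return supervised_loss_with_grad(pred, truth, config)[0]


def consistency_loss_with_grad(teacher_pred: np.ndarray, student_pred: np.ndarray,
                               valid: Optional[np.ndarray] = None
                               ) -> Tuple[float, np.ndarray]:
    """Mean squared error between probability maps over valid pixels/classes.

    ``valid`` is an optional (B,H,W) / (H,W) boolean mask (e.g. the ROI);
    the gradient is with respect to the student map (the teacher is treated
    as a constant target).
    """
    t = np.asarray(teacher_pred, dtype=np.float64)
    s = np.asarray(student_pred, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError(f"shape mismatch: teacher {t.shape}, student {s.shape}")
    diff = s - t
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.ndim == t.ndim - 1:
            valid = np.expand_dims(valid, axis=-3)
        diff = diff * valid
        n = int(valid.sum()) * t.shape[-3]
        if n == 0:
            raise ValueError("consistency_loss: no valid pixels")
    else:
        n = diff.size
    loss = float((diff * diff).sum() / n)
    return loss, 2.0 * diff / n


def consistency_loss(teacher_pred: np.ndarray, student_pred: np.ndarray,
                     valid: Optional[np.ndarray] = None) -> float:
    return consistency_loss_with_grad(teacher_pred, student_pred, valid)[0]


def lambda_schedule(step: int, config: LossConfig) -> float:
    """Gaussian ramp-up lambda(step) = lambda_max * exp(-5 (1 - min(step/L, 1))^2).

    Monotone non-decreasing in ``step``; equal to lambda_max from step ==
    ramp_length onward. Restarted at the beginning of every training round.
    """
    if config.ramp_length <= 0:
        raise ValueError(f"ramp_length must be positive, got {config.ramp_length}")
    if step < 0:
        raise ValueError(f"step must be >= 0, got {step}")
    t = min(step / config.ramp_length, 1.0)
    return float(config.lambda_max * np.exp(-5.0 * (1.0 - t) ** 2))


def total_loss(sup: float, con: float, lam: float) -> float:
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return sup + lam * con


def beta_inverse_frequency(records: Sequence, n_classes: int) -> np.ndarray:
    """Per-class weights proportional to inverse pixel frequency in the given
    labeled records, renormalized to mean 1. Only human-provenance labels
    should be passed in (pseudo-labels are excluded upstream to avoid drift);
    classes absent from the set get the largest observed weight."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for rec in records:
        if rec.label is None:
            continue
        lab = rec.label[rec.label != IGNORE_LABEL]
        counts += np.bincount(lab.ravel(), minlength=n_classes)[:n_classes]
    if counts.sum() == 0:
        return np.ones(n_classes)
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), np.nan)
    inv = np.where(np.isnan(inv), np.nanmax(inv), inv)
    return inv / inv.mean()


def validate_probability_map(pred: np.ndarray, atol: float = 1e-5) -> None:
    pred = np.asarray(pred)
    if np.any(pred < -atol):
        raise ValueError("probability map has negative entries")
    sums = pred.sum(axis=-3)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError("class probabilities do not sum to 1")
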