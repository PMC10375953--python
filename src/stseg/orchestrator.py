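"""The iterative semi-supervised training procedure.

One *round* trains a fresh mean-teacher pair on the current labeled set and
unlabeled pool (1 labeled + 3 unlabeled slices per batch by default), saving
Q teacher snapshots at 25/50/75/100% of the round's steps. At the end of a
round the snapshot ensemble stability-scores every remaining unlabeled image;
the top fraction (default 25% of the remaining pool, at least 1) is admitted
to the labeled set with the final teacher's masks as pseudo-labels, and the
next round retrains from scratch on the expanded set. The consistency weight
ramps up from ~0 to lambda_max within every round.

Every source of randomness is derived from (seed, round, step) keys, so runs
are exactly reproducible and individual steps can be replayed in isolation.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import evaluation as E
from . import losses as L
from . import mean_teacher as MT
from . import network as N
from . import selection as S
from .records import DatasetState


@dataclass
class RunConfig:
    network: N.NetworkConfig = field(default_factory=N.NetworkConfig)
    max_rounds: int = 3
    epochs_per_round: int = 20
    batch_labeled: int = 1
    batch_unlabeled: int = 3
    q_checkpoints: int = 4
    selection_fraction: float = 0.25
    seed: int = 0
    lr: float = 3e-3
    noise_sd: float = 0.05
    rho: float = 0.75
    gamma: float = 2.0
    lambda_max: float = 1.0
    ramp_fraction: float = 0.4       # lambda reaches its max after this share of a round
    # Desk-scale EMA: a round here is a few hundred steps, not a few hundred
    # thousand, so the ramp-up alpha is lowered and the ramp-up phase extended
    # to half a round so the teacher can actually track the student within a
    # round. EMAConfig itself defaults to the full-scale values (0.99/0.999).
    ema_alpha_rampup: float = 0.95
    ema_alpha_main: float = 0.999
    ema_rampup_fraction: float = 0.5
    beta_mode: str = "inverse_freq"  # "uniform" | "inverse_freq"

    def __post_init__(self) -> None:
        if self.max_rounds < 1 or self.q_checkpoints < 2:
            raise ValueError("max_rounds >= 1 and q_checkpoints >= 2 required")
        if self.batch_labeled < 1:
            raise ValueError("batch composition needs >= 1 labeled member")
        if not 0.0 <= self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in [0, 1]")


@dataclass
class RoundState:
    round_index: int
    dataset: DatasetState
    ensemble: Optional[S.CheckpointEnsemble] = None
    pair: Optional[MT.ModelPair] = None
    val_report: Optional[E.DiceReport] = None
    loss_log: List[Dict[str, float]] = field(default_factory=list)
    admitted: List[str] = field(default_factory=list)
    scores: List[S.StabilityScore] = field(default_factory=list)
    error: Optional[str] = None


def effective_composition(dataset: DatasetState,
                          composition: Tuple[int, int]) -> Tuple[int, int]:
    """The composition actually used: with an empty unlabeled pool the batch
    degrades to all-labeled; the labeled count never exceeds the labeled set."""
    n_lab, n_unl = composition
    if n_lab < 1:
        raise ValueError("composition needs >= 1 labeled slot")
    if not dataset.unlabeled:
        n_lab, n_unl = n_lab + n_unl, 0
    return min(n_lab, max(1, len(dataset.labeled))), n_unl


def epoch_sampler_rng(seed: int, round_index: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, round_index, epoch, 0x5A]))


def batch_sampler(dataset: DatasetState, composition: Tuple[int, int],
                  rng: np.random.Generator
                  ) -> Iterator[Tuple[dict, dict]]:
    """One epoch of batches. Every batch satisfies the composition exactly
    (labeled count, unlabeled count); the labeled records are visited at least
    once per epoch (the final batch wraps around); unlabeled members are
    sampled uniformly. With an empty pool the composition degrades to
    (labeled + unlabeled, 0)."""
    labeled, unlabeled = dataset.labeled, dataset.unlabeled
    if not labeled:
        raise ValueError("batch_sampler: empty labeled set")
    n_lab, n_unl = effective_composition(dataset, composition)
    order = rng.permutation(len(labeled))
    n_batches = math.ceil(len(labeled) / n_lab)
    for b in range(n_batches):
        idx = [order[(b * n_lab + i) % len(labeled)] for i in range(n_lab)]
        lab = [labeled[i] for i in idx]
        labeled_batch = {
            "images": np.stack([r.image for r in lab]),
            "labels": np.stack([r.label for r in lab]),
            "roi": np.stack([r.roi for r in lab]) if lab[0].roi is not None else None,
        }
        if n_unl:
            uidx = rng.integers(0, len(unlabeled), size=n_unl)
            unl = [unlabeled[i] for i in uidx]
            unlabeled_batch = {
                "images": np.stack([r.image for r in unl]),
                "roi": np.stack([r.roi for r in unl])
                if unl[0].roi is not None else None,
            }
        else:
            unlabeled_batch = {"images": np.zeros((0,) + lab[0].image.shape,
                                                  dtype=np.float32)}
        yield labeled_batch, unlabeled_batch


def round_loss_config(config: RunConfig, dataset: DatasetState,
                       total_steps: int) -> L.LossConfig:
    beta = None
    if config.beta_mode == "inverse_freq":
        # human labels only: pseudo-labels are excluded to avoid drift
        beta = L.beta_inverse_frequency(dataset.human_labeled,
                                        config.network.n_classes)
    return L.LossConfig(
        rho=config.rho, gamma=config.gamma, beta=beta,
        lambda_max=config.lambda_max,
        ramp_length=max(1, int(config.ramp_fraction * total_steps)))


def round_ema_config(config: RunConfig, total_steps: int) -> MT.EMAConfig:
    return MT.EMAConfig(
        alpha_rampup=config.ema_alpha_rampup, alpha_main=config.ema_alpha_main,
        rampup_steps=int(config.ema_rampup_fraction * total_steps))


def checkpoint_steps(total_steps: int, q: int) -> List[int]:
    """Snapshot after these (1-based) steps: 1/q, 2/q, ..., q/q of the round."""
    steps = sorted({max(1, round(total_steps * j / q)) for j in range(1, q + 1)})
    while len(steps) < q:   # degenerate short rounds: pad with the final step
        steps.append(total_steps)
    return steps


def run_round(state: RoundState, config: RunConfig) -> RoundState:
    """Train a (fresh) mean-teacher pair for one round and snapshot Q teacher
    checkpoints; evaluates the final teacher on the validation split."""
    dataset = state.dataset
    r = state.round_index
    if not dataset.labeled:
        raise ValueError("run_round: empty labeled set")
    if config.epochs_per_round <= 0:
        pair = MT.make_pair(config.network, seed=_round_seed(config.seed, r))
        return replace(state, pair=pair, error="epochs_per_round == 0: untrained")
    if not dataset.unlabeled:
        warnings.warn("unlabeled pool empty: degrading to supervised-only "
                      "training for this round", stacklevel=2)

    n_lab, _ = effective_composition(
        dataset, (config.batch_labeled, config.batch_unlabeled))
    batches_per_epoch = math.ceil(len(dataset.labeled) / n_lab)
    total_steps = batches_per_epoch * config.epochs_per_round
    loss_config = round_loss_config(config, dataset, total_steps)
    ema_config = round_ema_config(config, total_steps)

    pair = MT.make_pair(config.network, seed=_round_seed(config.seed, r))
    opt = MT.init_optimizer(pair.student, lr=config.lr)
    snap_at = checkpoint_steps(total_steps, config.q_checkpoints)
    snapshots, provenance = [], []
    loss_log: List[Dict[str, float]] = []

    step = 0
    snap_idx = 0
    for epoch in range(config.epochs_per_round):
        sampler_rng = epoch_sampler_rng(config.seed, r, epoch)
        for labeled_batch, unlabeled_batch in batch_sampler(
                dataset, (config.batch_labeled, config.batch_unlabeled),
                sampler_rng):
            rng_s, rng_t = MT.step_rngs(config.seed, r, step)
            log = MT.training_step(pair, labeled_batch, unlabeled_batch,
                                   loss_config, ema_config, opt,
                                   rng_s, rng_t, noise_sd=config.noise_sd)
            loss_log.append(log)
            step += 1
            while snap_idx < len(snap_at) and snap_at[snap_idx] == step:
                snapshots.append(N.snapshot(pair.teacher))
                provenance.append((r, step))
                snap_idx += 1
    while len(snapshots) < config.q_checkpoints:
        snapshots.append(N.snapshot(pair.teacher))
        provenance.append((r, step))

    ensemble = S.CheckpointEnsemble(config=config.network,
                                    checkpoints=snapshots,
                                    provenance=provenance)
    val_report = None
    if dataset.val:
        val_report = E.evaluate_split(pair.teacher, dataset.val,
                                      config.network.n_classes, round_index=r)
    return replace(state, pair=pair, ensemble=ensemble, val_report=val_report,
                   loss_log=loss_log)


def _round_seed(seed: int, round_index: int) -> int:
    return int(np.random.SeedSequence([seed, round_index, 0x1717]
                                      ).generate_state(1)[0] % (2 ** 31))


def run_pipeline(initial: DatasetState, config: RunConfig
                 ) -> List[RoundState]:
    """Steps 1-5: train; stability-score the pool; admit the top fraction as
    pseudo-labels; retrain on the expanded set; repeat for max_rounds."""
    initial.check_disjoint()
    dataset = initial
    rounds: List[RoundState] = []
    for r in range(1, config.max_rounds + 1):
        state = run_round(RoundState(round_index=r, dataset=dataset), config)
        if state.error:
            rounds.append(state)
            break
        if dataset.unlabeled and config.selection_fraction > 0:
            scores = S.score_pool(dataset.unlabeled, state.ensemble)
            selected = S.rank_and_select(scores, config.selection_fraction)
            masks = {s.image_id: s.pseudo_mask for s in scores}
            dataset = S.update_datasets(dataset, selected,
                                        {i: masks[i] for i in selected},
                                        round_index=r)
            state = replace(state, scores=scores, admitted=list(selected))
        rounds.append(state)
        dataset_ids = dataset.ids("labeled") | dataset.ids("unlabeled")
        initial_ids = initial.ids("labeled") | initial.ids("unlabeled")
        assert dataset_ids == initial_ids, "image ids lost or duplicated"
    return rounds


def run_supervised_baseline(dataset: DatasetState, config: RunConfig
                            ) -> List[RoundState]:
    """The supervised-only baseline: same network and supervised loss, one
    round, no unlabeled data, no consistency term, no pseudo-labels."""
    sup_dataset = DatasetState(labeled=list(dataset.labeled), unlabeled=[],
                               val=dataset.val, test=dataset.test)
    sup_config = replace(config, max_rounds=1, lambda_max=0.0,
                         selection_fraction=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # intentional empty-pool degradation
        state = run_round(RoundState(round_index=1, dataset=sup_dataset),
                          sup_config)
    return [state]


def subsample_unlabeled(dataset: DatasetState, fraction: float,
                        seed: int = 0) -> DatasetState:
    """Keep a seeded random fraction of the unlabeled pool (for ablations)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB1A]))
    n_keep = int(round(fraction * len(dataset.unlabeled)))
    keep = sorted(rng.permutation(len(dataset.unlabeled))[:n_keep])
    return DatasetState(labeled=list(dataset.labeled),
                        unlabeled=[dataset.unlabeled[i] for i in keep],
                        val=dataset.val, test=dataset.test)
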