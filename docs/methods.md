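# Methods

## Problem setting

`stseg` targets multi-class semantic segmentation of stacked 2-D grayscale
slices (CT-style volumes) under *sparse slice-wise annotation*: in each volume
only a few slices carry a dense, expert-grade label mask, while the slices
immediately above and below each labeled slice (±3 by default) form an
unlabeled pool. Because adjacent slices are strongly correlated, that pool
carries nearly the same content as the labeled slices and is the natural
target for semi-supervised learning. All learning and evaluation is restricted
to an organ region of interest (ROI); pixels outside the ROI carry the
reserved ignore value 255 and never enter a loss or metric.

## Model and training procedure

**Mean-teacher coupling.** Two networks of identical architecture are
maintained: a student trained by gradient descent and a teacher whose
parameters are an exponential moving average (EMA) of the student's,

    θ*_z = α θ*_{z−1} + (1 − α) θ_z .

Only the student receives gradients. Each training batch contains 1 labeled
and 3 unlabeled slices; teacher and student each see an independently
perturbed view (fresh additive Gaussian input noise, σ = 0.05; dropout 0.5 on
the student's last feature map). The loss is

    L_total = L_sup + λ · L_con ,

where `L_sup = (1 − ρ) L_dice + ρ L_focal` is computed on the labeled batch
members and `L_con` is the mean squared error between teacher and student
class-probability maps on **all** members (ROI-restricted). ρ = 0.75 and the
focal focusing exponent γ = 2 by default. The per-class focal weights β_t
default to inverse pixel frequency computed from the *human*-labeled records
only (pseudo-labels are excluded so admitted masks cannot drift the weights),
renormalized to mean 1. λ follows the Gaussian ramp
`λ(z) = λ_max · exp(−5 (1 − min(z/L, 1))²)`, restarted at the beginning of
every round, with the ramp length L set to 40% of a round's steps.

**Selective re-training.** A run consists of `max_rounds` (default 3) rounds.
Each round trains a *fresh* student/teacher pair (re-initialization rather
than warm start, in the spirit of selective re-training curricula) and saves
Q = 4 teacher snapshots at 25/50/75/100% of the round's steps. At the end of
a round every remaining unlabeled image is scored by pseudo-mask stability:

    s_i = Σ_{j=1}^{Q−1} meanIOU(Y_ij, Y_iQ) ∈ [0, Q−1] ,

where Y_ij is the argmax mask predicted by snapshot j with all perturbations
off, and meanIOU averages per-class intersection-over-union over the classes
present in either mask (avoiding undefined 0/0 terms for absent classes).
The top 25% of the *remaining* pool (floor, minimum 1; ties broken by
ascending image id) is admitted to the labeled set, carrying the final
snapshot's mask as a pseudo-label; admitted records keep a provenance tag and
are never allowed to displace or overwrite a human label. `|D_l| + |D_u|` is
conserved across rounds. Selection also runs after the final round, so a run's
report always contains a full quota sequence (e.g. 10, 7, 5 admissions for a
40-image pool at 25%).

**Dice loss form.** The supervised dice term is the standard soft multi-class
dice loss `1 − (1/T′) Σ_t 2 Σ p_t y_t / (Σ p_t² + Σ y_t² + ε)` with ε = 1e−6,
reduced per class over the whole batch and averaged over the T′ classes
present in the truth (empty classes skipped).

**Evaluation.** All reported numbers come from the *teacher* under
unperturbed inference. The metric is the per-class dice coefficient
`2|X∩Y|/(|X|+|Y|)`, aggregated as mean ± sd across the images of a split
(classes absent from both prediction and truth are skipped for that image)
and summarized by the class-mean average. The supervised-only (SupOnly)
baseline uses the same network and supervised loss, trains for one round's
epoch budget on the labeled slices alone (batches of 4 labeled members), and
is evaluated identically.

## Networks

Two backbones, both mapping (B, 1, H, W) → (B, T, H, W):

* **tiny** (default): a two-level encoder/decoder with a skip connection,
  ~8k parameters at width 16 — sized so a full CPU experiment finishes in
  minutes.
* **multires**: a miniature parallel multi-resolution network — a
  full-resolution stream maintained end to end, 2–3 lower-resolution streams
  in parallel, and repeated cross-resolution fusion (resize-and-sum with 1×1
  projections) at every exchange block. It keeps the two defining properties
  of high-resolution segmentation backbones at desk scale; a full-scale
  reproduction of such a backbone is out of scope.

The training stack (reverse-mode autodiff with im2col convolutions, RMSProp,
EMA) is implemented directly on NumPy in `stseg.tape`; gradient correctness is
pinned by finite-difference tests, and the loss gradients are analytic and
tested the same way.

## Numerical and procedural choices

* **Optimizer**: RMSProp (adaptive, momentum-free), lr 3e−3, decay 0.99,
  with global gradient-norm clipping at 5.0 — single-labeled-slice batches
  make raw gradient norms heavy-tailed, and clipping removes the rare
  divergent round.
* **EMA horizon at desk scale**: the canonical coefficients (α = 0.99 during
  ramp-up, 0.999 after) assume rounds of hundreds of thousands of steps. A
  desk-scale round here is a few hundred steps, over which a 0.999-EMA
  teacher would barely leave its initialization. `RunConfig` therefore
  defaults to α = 0.95 during a ramp-up phase covering the first half of each
  round, then 0.999; `EMAConfig` keeps the canonical 0.99/0.999 defaults for
  users training at full scale.
* **Determinism**: every random draw derives from `(seed, round, step, role)`
  keys via `SeedSequence`, so runs are bit-reproducible and any step can be
  replayed in isolation; the same derivation makes the degenerate pipeline
  (λ = 0, no selection, one round) bit-identical to a plain supervised loop.
* **Degenerate inputs**: an empty labeled set is an error; an empty unlabeled
  pool degrades to supervised training (batch composition 4+0) with a
  warning; an all-ignore mask is an error in every loss and metric;
  `epochs_per_round = 0` returns an untrained model with an error flag.
* **Probabilities** are clamped to [1e−7, 1−1e−7] before logarithms; the
  focal per-pixel sum runs over all T one-vs-rest terms by default, with a
  `focal_true_class_only` switch for the true-class-only reading.

## Synthetic benchmark

The generator emulates the sparse-annotation regime without any external
data. Each volume: an ROI of two wobbled ellipse-like blobs (lung-like); class
regions as the argmax of per-class smooth Gaussian random fields, warped from
slice to slice by a small random elastic displacement so adjacent slices are
highly correlated; per-class textures = base intensity + a zero-mean
structured pattern (smoothed fields, speckle, cosine cell lattices, oriented
striations, thresholded blob clusters) + i.i.d. Gaussian noise. Structured
patterns are centered within the visible region so the regional mean equals
the class's base intensity. The default benchmark uses 4 texture classes at
64×64 (an 8-class mode exists but is not the default, to keep CPU runs fast),
12 volumes of 21 slices split 8/2/2 by volume, 3 labeled slices per volume
with a ±3 neighbour window — 24 labeled and 144 unlabeled training slices.
With 6 neighbours per labeled slice this regime caps the unlabeled:labeled
ratio at 6:1; the pool is therefore ~144, not arbitrarily large.

What the benchmark does *not* emulate: anatomy, 3-D lesion continuity beyond
smooth boundary drift, scanner artifacts, inter-patient appearance shifts, or
class co-occurrence statistics of real pathology. Passing results show the
pipeline's machinery (losses, EMA, stability selection, bookkeeping) works
and that unlabeled neighbours help on correlated textured data; they do not
certify clinical segmentation quality.

## Scale of the shipped experiments

Desk-scale defaults are 20 epochs per round (a few hundred optimizer steps
per round on the default benchmark), chosen so a full three-round,
three-seed comparison against the supervised-only baseline completes in
minutes on one CPU. The semi-supervised benefit is asserted as a mean over
three seeds; the improvement-with-unlabeled-fraction ablation reports a
trend only, since individual cells are stochastic at this scale.

## Known limitations

* Inter-slice correlation is exploited only through the data regime; the
  model itself is strictly 2-D.
* Stability selection admits whole images; there is no pixel-level
  confidence filtering within an admitted image, so a stable-but-wrong mask
  is admitted wholesale.
* The benchmark's classes are separable by local texture statistics; real
  diffuse-lung-pattern classes overlap far more.
* At desk scale the teacher EMA horizon had to be shortened (see above);
  full-scale coefficient choices are untested here.
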