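# Methods

## Problem and model

`fedsynth` simulates cross-silo federated training of a deep convolutional
GAN (DCGAN) for grayscale medical image synthesis. K clinical silos hold
severity-graded images (grades 0–4, none → severe) with strongly non-IID
label distributions; none may share raw data. A coordinating server runs
federated averaging (FedAvg): each round *t* it distributes the global
generator and discriminator weights θ_G^t, θ_D^t, every client k trains both
networks locally for E epochs on its shard 𝒟_k, and the server replaces the
globals with the dataset-size-weighted average

  θ^{t+1} = Σ_k (|𝒟_k| / Σ_j |𝒟_j|) · θ_k^{t+1},

applied layer-wise to *both* networks, batch-norm running statistics
included (uniform 1/K averaging is available as a config mode). Locally each
client plays the standard minimax game: the discriminator minimises a
label-smoothed binary cross-entropy (real target 0.9, fake target 0) and the
generator minimises the non-saturating loss −E[log D(G(z))]. Before any
federated round the globals can be warm-started by a short centralized
pretraining run on a morphologically different domain (CT-like images),
transferring generic low-level image statistics to the smaller fine-tuning
domain.

### Architecture

Generator: z ∈ ℝ^200 (standard normal) → dense → 8×8×256 stem → stride-2 4×4
transposed-conv blocks with filters (128, 64, 32, 1) at 128×128 output;
batch norm + ReLU on hidden blocks, tanh output. Discriminator: stride-2 4×4
conv blocks with filters (32, 64, 128, 256), LeakyReLU(0.2), batch norm from
the second block on, flatten → dense(1) → sigmoid. For smaller outputs the
8×8×256 stem is kept and blocks are dropped from the wide end, so a
16×16 model has one block per network. Optimizer: Adam(lr 2e-4, β₁ 0.5,
β₂ 0.999), weight init N(0, 0.02). All of this runs on a small numpy layer
library (`fedsynth.nn`) with hand-written backward passes, each verified
against central finite differences in the test suite.

## Preprocessing

Raw images pass through a fixed deterministic chain: tensorize on the 0–255
scale → bilinear anti-aliased resize to S×S → BT.601 grayscale
(0.299, 0.587, 0.114) → CLAHE on the 8-bit image → normalise to [0,1] →
gamma correction x↦x^γ (default γ = 1.2) → quantization to 16 gray levels →
rescale to [−1, 1] via x↦2x−1. CLAHE clips each tile histogram at
`clip_limit · tile_area / 256` counts (default clip 2.0, 8×8 tiles),
redistributes the excess uniformly, and interpolates the per-tile mappings
bilinearly. Quantization uses round-half-up: x ↦ ⌊x·(L−1)+0.5⌋/(L−1), so
0.5 at 16 levels maps to 8/15. Degenerate inputs (sides < 8 px, non-finite,
or constant) are logged and skipped rather than fatal. Processed images are
stored in TFRecord-framed files (length + masked CRC32C + a small
protobuf-style message), with an NPZ container behind the same read/write
contract; round-trips are float32-lossless and order-preserving.

## Non-IID partitioning

Each severity label is assigned to exactly 2 uniformly chosen clients, and
every sample of that label flips a fair coin between them — emulating
clinics specialising in particular grades while retaining overlap. A
rebalancing pass then enforces a floor T = ⌈min_frac·|𝒟|⌉ (default
min_frac 0.01): while any shard is below T, randomly chosen samples move
from the currently largest shard to the currently smallest (ties broken by
lowest client id). Each move transfers min(T − |smallest|, |largest| − T)
samples so the donor never drops below T itself; feasibility (K·T ≤ |𝒟|)
guarantees termination. Label locality (≤ 2 holders per label) is an
invariant of the assignment stage only — rebalancing may break it.

## Evaluation

* **Realism** — mean probability a *frozen* discriminator, taken from a
  non-federated DCGAN trained on the full centralized dataset, assigns to
  n = 256 fixed-seed generator samples (eval-mode forward passes).
* **FID** — ‖μ_r−μ_f‖² + Tr(Σ_r + Σ_f − 2(Σ_r Σ_f)^{1/2}) between Gaussian
  fits of embedded real and synthetic images, with 1e-6·I covariance
  regularization and truncation of residuals above −1e-6. The embedding is
  pluggable; the built-in one is a fixed-seed random-projection
  convolutional map (two 3×3 conv layers, ReLU, per-channel spatial
  mean+std, d = 32), which requires no downloaded weights. Absolute FID
  values are therefore not comparable to InceptionV3-based numbers; only
  within-study comparisons are meaningful.
* **Loss variance** — sample mean ± sd (n−1 denominator) of the pooled
  per-batch loss series for each client configuration.

## Privacy audit

1. *Membership inference*: a small conv classifier (two stride-2 conv
   blocks → dense → sigmoid) is trained to separate real training images
   from generator samples; held-out accuracy (threshold 0.5) and AUC are
   reported. This is the real-vs-synthetic design, not the classic
   member-vs-non-member design: high scores conflate memorization with mere
   generator imperfection, which is documented as a caveat.
2. *Model inversion*: plain gradient descent on z (default 500 steps, step
   0.05, 5 restarts, best-so-far kept) minimising pixel MSE to each target;
   the mean best loss over targets is reported.
3. *Empirical ε*: max over ROC thresholds of ln(TPR/FPR), with TPR floored
   at 1/n₊ and FPR at 1/n₋, so a perfect finite-sample attack yields ln n
   rather than ∞. The estimator is a plug-in maximum of a log ratio and
   carries a positive finite-sample bias (≲ 1 nat at test sizes of a few
   dozen per class); it is a distinguishability index, not a certified DP
   bound. A two-sided variant adding ln((1−FPR)/(1−TPR)) is available via
   `two_sided=True`.
4. *Minimum-distance analysis*: per-pixel RMS distance in [−1, 1] space from
   each synthetic image to its nearest real image (resolution-independent);
   mean/min/max over the synthetic set.

Composite risk = 100·[0.4·AUC + 0.2·accuracy + 0.2·(1−min(inv,1)) +
0.2·(1−min(dist,1))], higher = more leakage. The weights are explicit
configuration: the score is a convenience aggregate, not a calibrated risk
probability.

## Synthetic phantoms

Two domains, both 8-bit grayscale with a constant background outside the
anatomy mask:

* **fundus-like** — circular field of view (radius 0.48·S), radial
  vignette, 2–4 dark vessel-like random walks from the centre, and a
  Poisson(λ(grade)) number of lesions (bright "exudate" discs and dark
  "hemorrhage" blobs, radii 2–5 px at 128×128, scaled proportionally);
  λ(grade) = 3·grade, so grade 0 has none and the count rises with severity.
* **CT-like** — elliptical body outline with a bright rim and 3–6 smooth
  interior ellipses, no lesions.

The domains share low-level statistics (smooth grayscale anatomy on dark
background) but not high-level structure, which is exactly the transfer
premise of CT pretraining. These are statistical stand-ins: passing tests
show the machinery behaves correctly under the assumed severity/label-skew
structure, not that the framework produces clinically useful retinal images.

## Desk-scale reference configuration

The full study runs on a single CPU at 16×16 resolution: 192 fundus-like
phantoms for fine-tuning, 192 CT-like phantoms for pretraining (1 epoch),
K = 3 clients, T = 2 rounds, E = 1 local epoch. Two scaled parameters
deserve justification:

* batch size 8 (not the full-scale 64), scaled with the 8× reduction in
  image side so one local epoch performs a meaningful number (~8) of
  optimizer steps;
* the centralized baseline is trained to its adversarial plateau
  (40 epochs ≈ 960 updates) before its discriminator is frozen as the
  realism scorer, because a scorer must actually discriminate: at the
  plateau it orders real phantoms (≈0.45) above untrained-generator output
  (≈0.42), whereas a 5-epoch desk baseline scores everything ≈0.50.

### Known limitation of the frozen-scorer realism metric

At this optimization depth the frozen scorer's response to sample quality is
*non-monotone*: untrained gray output ≈0.421, partially-trained output
≈0.410, plateau-quality fakes ≈0.451 ≈ real ≈0.452. Two federated rounds of
one epoch land the generator in that middle valley, so its realism score can
*drop* even while the generator demonstrably approaches the data (FID falls
by an order of magnitude, e.g. ≈39.6 → ≈3.3 at seed 1, and the output
variance rises toward the real value in the same runs — both recomputed by
`scripts/acceptance.py`). Realism comparisons
between matched runs (e.g. pretrained vs random initialization, which share
shards, seeds and scorer) remain meaningful; absolute realism movements over
very short trainings do not. With the full-scale budget (T·E = 10 local
epochs) the generator passes through the valley.

## Numerical choices

Probabilities are clamped to [1e-7, 1−1e-7] before logarithms. Batch-norm
uses eps 1e-5 and momentum 0.9; its running statistics are part of the
exchanged weight sets and are averaged with the same FedAvg coefficients as
trainable weights. Per-client, per-round seeds come from
`SeedSequence(seed, spawn_key=(round, client_id))`, making full runs
reproducible bit-for-bit on a single thread while avoiding repeated batch
orders across rounds. Argmax/argmin ties in rebalancing are broken by lowest
client id. fedavg asserts elementwise convexity (output within the clients'
envelope) every round.
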