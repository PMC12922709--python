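# Methods

## The training scheme

`uatseg` trains a binary segmentation network with a pixel-weighted binary
cross-entropy in which the weights come from the model's own uncertainty,
refreshed every batch:

1. **Warmup.** For epochs `1..n_warmup` every method — including the
   conformal one, whose calibration would otherwise be meaningless on an
   untrained model — optimises plain BCE. Weighting starts at epoch
   `n_warmup + 1`. Because no uncertainty computation touches the random
   stream, the warmup trajectory of any method is bit-identical to a
   baseline run under the same seeds; the test suite asserts this.
2. **Weighting.** After warmup, each batch's uncertainty map `U` is
   computed from the current model's predictions and the loss becomes
   `-(1/N) Σ W_i [Y ln Ŷ + (1-Y) ln(1-Ŷ)]` with `W = 1 + γU`. The
   normalisation is by pixel count `N`, not by `ΣW`, so the loss scale
   grows with `γ`; early stopping is therefore driven by the unweighted
   loss, which is computed in the same pass.
3. **Conformal recalibration.** The LAC quantile `q̂` is fitted on the
   calibration split at the end of epoch `n_warmup` and refitted after
   every further `n_warmup` epochs (refits at `n_warmup, 2·n_warmup, …`,
   logged in `q_hat_history` so the schedule is auditable). Between refits
   `q̂` is frozen but prediction sets are computed per batch from current
   predictions.
4. **Early stopping.** Best epoch = first minimum of the unweighted
   validation loss; training halts once `patience` epochs pass without
   strict improvement (a tie is not an improvement). The best-validation
   checkpoint is restored before test evaluation.

### Gradient treatment of the weights

Weights are computed from detached predictions: they are plain numbers, not
differentiable functions of the parameters. Backpropagation therefore sees
`W` as a constant — the model cannot lower its loss by suppressing its own
uncertainty instead of fixing its errors. In this implementation gradients
are hand-derived, so the property holds by construction; a test verifies
that supplying the same numeric weights as constants reproduces the update
bit-for-bit.

### Uncertainty map conventions

* **Entropy** uses natural logs (the choice of base only rescales `γ`) and
  the `0·log 0 := 0` convention via `xlogy`, so saturated pixels have
  exactly zero entropy; maps are bounded by `ln 2 ≈ 0.693`.
* **Variance** across the `M` heads is the population (divide-by-`M`)
  variance, computed in shifted-data form so that identical heads give
  exactly 0; it is bounded by 0.25.
* **Conformal** maps are binary: a pixel is uncertain when its two-class
  prediction set is empty or contains both classes. A graded encoding
  (e.g. margin to the threshold) would also be defensible; the binary one
  is the minimal faithful mapping from set size to a scalar for K = 2.
  The quantile is the `⌈(1-α)(n+1)⌉`-th order statistic without
  interpolation — the form for which the finite-sample coverage guarantee
  is stated — and clamps to 1 (full sets everywhere) when the rank exceeds
  the pool size. Calibration scores are pooled over all pixels of all
  calibration images; pools above 10⁶ pixels are subsampled with a stored
  seed to bound memory without breaking exchangeability.

### Loss numerics

Probabilities entering logs are clamped to `[1e-7, 1-1e-7]`. The clamp
bounds the derivative rather than zeroing it: a confidently-wrong saturated
pixel keeps a (large but finite) corrective gradient. Zeroing it instead
permanently freezes saturated output heads — an effect we observed as
dead heads stuck at probability 0.

## The fixture model

The reference task fine-tunes a large prompted foundation model on GPUs;
that is out of scope here. The fixture is a compact U-Net-style
encoder–decoder (default: depth 2, base width 8, ≈ 15k parameters, float64
numpy, CPU) with `M = 3` parallel 1×1-convolution output heads sharing one
backbone — the cheapest architecture that yields a nondegenerate
head-variance signal, mirroring a model that natively emits several
candidate masks. The primary probability map — used for the loss, entropy,
conformal scores and Dice — is the arithmetic mean of the head
probabilities (a symmetric, deterministic convention; which single native
output the reference pipeline uses is unknowable from outside).

Two initialisation details matter:

* Head biases start at −2, the logit of a ≈ 0.1 foreground prior. With
  zero-bias init, the class imbalance drives all heads strongly negative in
  the first epochs and the mean-of-sigmoids loss then cannot revive
  individually saturated heads (their own `σ'` vanishes even while the
  mean recovers); prior-matched bias init removes this failure mode. This
  is the standard remedy for rare-foreground detection heads.
* Head weights are randomly initialised per head (seeded). Zero-init heads
  would receive identical gradients forever and make the variance method
  degenerate by symmetry; the zero-init option exists for testing the
  `sigmoid(0) = 0.5` contract only.

Optimisation is Adam with classic L2 weight decay added to the gradient.
The config defaults mirror the reference protocol (learning rate and weight
decay 1e-5, batch size 1, patience 5, max 40 epochs). That 1e-5 is a
*fine-tuning* rate for a pretrained giant; the desk-scale experiments train
the small fixture from scratch and set 1e-3, the conventional Adam rate at
this scale — at 1e-5 the fixture's loss barely moves from its
initialisation over a 40-epoch budget and no foreground is ever predicted.

## Synthetic data

Three presets imitate the *geometry and boundary ambiguity* of the three
ophthalmic tasks — not their photometry; no claim of visual realism is
made, and passing tests say nothing about performance on real fundus/OCTA
images:

| preset | geometry | fg fraction | intensities |
|---|---|---|---|
| `ga_like` | union of 2–5 random ellipses (multi-lobed lesion) | 0.05–0.25 | bright on dark |
| `cup_like` | ellipse nested in a concentric brighter disc; the cup is foreground | 0.04–0.12 | bg 0.3 / disc 0.65 / cup 0.9 |
| `faz_like` | small central dark blob plus radial dark vessel lines | 0.01–0.05 | dark on bright |

Each sample: draw the clean shape (rejection-sampled until the stored
mask's foreground fraction is in range, ≤ 100 attempts), render the
intensity image, Gaussian-blur the edge (`boundary_sigma`, default 1.5 px),
add clipped Gaussian noise (sd 0.05), and — the key ingredient — flip mask
labels independently with probability 0.5 inside a band of half-width
`label_flip_band` (default 1.5 px) around the true edge. The flips are
irreducible annotation noise concentrated at the boundary, exactly the
ambiguity the weighting scheme is meant to exploit; they also cap the
attainable Dice below 1. Defaults (64×64 images, 120 samples) keep a full
experiment within minutes on one CPU.

Splits follow the reference protocol's 50/40/10/10
train/test/calibration/validation *counts* (those are image counts of a
110-image dataset, not percentages — they sum to 110); the split spec
normalises them to fractions and apportions any `n` by the
largest-remainder rule, which reproduces 50/40/10/10 exactly at `n = 110`
and gives 54/44/11/11 at the default `n = 120`.

## Statistics

Dice uses the 0.5 probability threshold; empty-vs-empty masks score 1
(perfect agreement on absence), empty-vs-nonempty 0. Mann-Whitney is
two-sided, exact (enumeration-equivalent) for tie-free combined `n ≤ 12`
and a tie-corrected normal approximation otherwise; the mode used is
recorded in the output. Levene's test is mean-centered (Brown-Forsythe
median-centering available via a flag); the degenerate all-constant case
raises rather than returning NaN. Comparison tables report per-comparison
p-values with star conventions (* < 0.05, ** < 0.01, *** < 0.001) and no
multiple-testing correction, matching the reporting style they mirror.

## Seeding and reproducibility

Dataset seed, model-init seed and run seed are independent. A run's only
stochasticity is weight init and per-epoch shuffling, so identical seeds
reproduce records bit-exactly (fixed BLAS threading assumed). In the paired
comparison experiment, repeat `r` of baseline and of entropy-UAT share both
seeds: warmup trajectories coincide bit-for-bit and the Dice comparison is
paired. The sweep runner (`uatseg grid`) varies only the run seed across
repeats, as its plan format specifies; the canned comparison additionally
varies the model seed per repeat, since repeats differing only in shuffle
order understate training stochasticity.

## What the comparison experiment actually shows

On the cup-like preset the fixture exhibits a plateau phase: for the first
epochs the network predicts (near-)pure background — the prior-matched
optimum of an imbalanced BCE — before the foreground solution emerges. With
the protocol's patience of 5, some baseline seeds early-stop inside that
plateau and end with Dice 0; runs that escape it reach Dice ≈ 0.87 (the
boundary label flips cap the ceiling). Entropy weighting changes this
systematically: during the plateau the predictions sit near the prior, so
the entropy map is fairly uniform and the weights `1 + γU` act as a ≈ 1.5–2×
amplifier of the loss signal, pushing the model off the plateau sooner.
The mean-Dice advantage of entropy-UAT at this scale is therefore driven
largely by *training stability* — fewer collapsed runs — which is the
desk-scale analogue of the instability-reduction the method is reported to
give on real data. The boundary-concentration property is independent of
this: after convergence the entropy map's mass sits within ~2 px of the
true edge (band mean ≈ 0.6 nats vs interior ≈ 0.01).

## Problem sizes

The test suite runs the comparison experiment at 120 samples × 64×64 × 5
paired repeats; the acceptance script uses 3 repeats. Unit tests use 16–32
px images and ≤ 7 epochs. These sizes were chosen so the whole suite is a
desk-scale computation; they are stated here so results are read at the
scale they were computed.

## Known limitations

* The fixture network is ~15k parameters; absolute Dice values say nothing
  about foundation-model performance, only about the *relative* effect of
  uncertainty weighting at this scale.
* Only K = 2 (binary) prediction sets; LAC is the only conformal score
  implemented.
* The synthetic generator models geometry and boundary ambiguity, not
  intensity statistics of real modalities.
* Image-level (non-pixel) conformal prediction and alternative losses
  (Dice/focal hybrids) are out of scope.
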