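# Methods

## Problem and pipeline

`breathpd` estimates Parkinson's disease (PD) status and MDS-UPDRS severity
from one night of respiratory effort sampled at f_b = 10 Hz.  Nights come
from two acquisition domains: chest-belt traces from polysomnography (PSG)
sleep studies, and contactless wireless (RF-derived) breathing.  The pipeline
is:

1. **Screening and normalization** (`breathing_io`).  Nights shorter than
   2 h are dropped, as are distorted or absent recordings.  "Distorted" has
   no standard operational definition, so this package adopts three
   testable rules: more than 20% of samples at the clip bound, more than 25%
   of 30-s windows flat-lined (sd below 5% of the median window sd), or no
   spectral peak in the 0.1–0.5 Hz respiratory band exceeding 3x the 1–5 Hz
   floor.  Kept nights are clipped to [-6, +6] raw units and standardized to
   zero mean, unit sd (population convention; mean/sd computed on the
   clipped signal, in that order).
2. **qEEG labels** (`qeeg_labels`).  Where EEG (C4-M1) exists, every second
   receives a 4-vector of relative spectral power in the delta (0.5–4 Hz),
   theta (4–8 Hz), alpha (8–13 Hz) and beta (13–30 Hz) bands.  Each second's
   spectrum is a Hann-tapered 4-s periodogram centered on that second
   (shifted inward at the night's edges); band integration is half-open
   [lo, hi), so power at exactly 4/8/13 Hz belongs to the upper band, and
   the normalization denominator is the sum over the four bands only.
3. **Network** (`model_core`), trained multitask (`training`).
4. **Evaluation** (`evaluation`), **interpretation** (`interpretation`) and
   a **synthetic cohort simulator** (`synthetic_data`) that makes the whole
   system testable without clinical data.

## Network

The model runs on the package's own numpy compute engine (`_nn`): a small
reverse-mode autodiff tape with hand-written adjoints for the convolution,
SRU recurrence, normalization and upsampling primitives (each verified by
finite differences in the test suite), plus Adam.

* **Breathing encoder E**: a stride-5 convolutional stem (25-tap kernel, so
  sub-Hz structure is linearly resolvable before the first rectification),
  eight 1D bottleneck residual blocks (stride 2 at blocks 1/3/5/7), and
  three SRU layers.  Total temporal stride S = 80 samples: 10 Hz input
  becomes features at 0.125 Hz, one step per 8 s.
* **PD encoder G (attention pooling)**: two stride-1 convolutions produce a
  scalar score per step; a softmax over time (the normalization layer turns
  scores into weights) and the global feature g in R^d is the
  attention-weighted time average of the encoder features.  The scorer is
  zero-initialized so pooling starts uniform and learns to sharpen.
* **PD classifier M**: three fully connected layers + sigmoid; a night is
  called PD when the score exceeds 0.5.
* **Severity predictor N**: four fully connected layers per head (total
  MDS-UPDRS by default; subpart heads I–IV are drop-in replacements chosen
  at construction).  The head output passes through a fixed gain of
  25 MDS-UPDRS points per unit, so the MLP regresses on a standardized
  scale while reporting raw MDS-UPDRS.
* **qEEG decoder F**: three x2-upsampling deconvolution blocks (upsample +
  three convolutions with channel normalization, ReLU and a residual
  connection), UNet-style skip connections concatenating the SRU layer
  outputs, then two per-second 1x1 layers and a softmax over the four
  bands; 2^3 upsampling returns 0.125 Hz features to the 1 Hz label rate.
* **Domain discriminators D_PD / D_Control**: one small MLP per diagnosis
  group estimating p(belt | g).  Two discriminators are used because the
  class mix differs drastically between domains; a single one would be free
  to delete disease information while chasing the domain gap.

### Numerical choices that mattered

* **The encoder is norm-free.**  Per-night normalization (the only form of
  "batch" normalization available at one-night minibatches) equalizes every
  night's feature statistics — which deletes precisely the between-night
  amplitude/variability differences that discriminate PD.  With
  normalization in the encoder, training flatlines at chance.  Depth is
  stabilized instead by down-scaling each residual branch at init (blocks
  start near the identity).  Channel normalization is retained inside the
  decoder blocks, where per-night statistics are harmless.
* **SRU init gain.**  The gated running average and the highway mix each
  attenuate activations; naive 1/sqrt(c_in) weight init shrinks the 3-layer
  stack's output ~4x and starves the heads.  Weights use sqrt(3/c_in).
* Default widths (stem 12, blocks 16–32, d = 32) are a CPU sizing choice;
  every width is configuration.  Forward passes are deterministic in eval
  mode; dropout (default 0.3 on the pooled feature) is the only stochastic
  layer.

## Training

A step consumes one night (the natural minibatch for full-night inputs);
subjects are visited in shuffled order with their window nights processed
consecutively.  The composite loss per night combines, with availability
masking (a missing label contributes zero value *and* zero gradient):

* class-weighted cross-entropy on the PD logit (weights = inverse class
  frequency of the training split's nights);
* squared severity error on residuals standardized by sev_scale = 25
  MDS-UPDRS points (equivalently, a weighted regression loss with weight
  1/25^2 in raw units — raw-unit MSE is ~1600 at init and destabilizes the
  shared trunk);
* L2 on predicted vs observed qEEG relative powers (padded seconds masked);
* an adversarial domain term per diagnosis group (below);
* transductive consistency: the population variance of the subject's
  severity predictions within the 1-month window, on the same standardized
  scale.  Earlier nights of the subject enter as detached anchors, so every
  night is pulled toward the subject's other predictions.

Default weights: w_cls = 1, w_sev = 1 (standardized), w_qeeg = 1,
w_adv = 0.1, w_cons = 0.1.  Optimization: Adam, lr 1e-3 with cosine decay,
global gradient-norm clip 5, 30 epochs, random 5-min crops per night during
training (evaluation always uses full nights).  At clinical scale the
reference setting is lr 1e-4 without cropping; the desk-scale defaults are
sized for a single CPU.  Training is deterministic given (data, config,
seed).

### Adversarial mechanics

Plain gradient reversal at desk scale reliably entered the anti-prediction
failure mode: the encoder maximizes the discriminator's cross-entropy by
making it *confidently wrong* (CE driven to ~9), which leaves the domain
fully decodable.  The working formulation is alternating **domain
confusion**: the discriminators minimize their own cross-entropy on
detached, standardized features — including an epoch-end refit to
near-optimality on the epoch's feature buffer with a light ridge penalty
(0.02) so their logits stay calibrated — while the encoder drives the
(frozen) discriminator output toward 1/2.  Without the refit the
discriminator lags hopelessly; without the ridge its logits saturate and
the confusion term explodes.  `domain_adaptation_train_config()` packages
the strong-invariance recipe (w_adv = 10, 200 refit steps).  Gradient
reversal remains available (`adversarial_mode="grl"`).

### Calibration and ensembling

Training subjects are split (class-stratified) into four equal subsets;
each member trains on three and fits two Platt scalars (A, B) on the fourth
by minimizing the cross-entropy of sigma(A z + B), with z the pre-sigmoid
logit.  The fit is a damped Newton iteration started at the identity
(1, 0), so calibrated cross-entropy never exceeds the uncalibrated one.
Platt scaling consumes the logit rather than the probability: an affine map
of a probability through a sigmoid cannot even express the identity, and
logit-input Platt is the standard formulation.  The final score is the mean
of the four members' calibrated scores.

## Evaluation methodology

* ROC/AUC (Mann–Whitney concordance, ties at 1/2); sensitivity TP/(TP+FN)
  and specificity TN/(TN+FP) at threshold 0.5 with Clopper–Pearson exact
  95% CIs (Wilson optional).
* Pearson correlation computed from its definition.
* Multi-night aggregation: the median over a subject's nights in the month
  immediately after the baseline visit (even counts: mean of the two middle
  values).
* Test–retest reliability: nights are split into consecutive
  non-overlapping windows of w nights; window medians are repeated
  measurements in a one-way random-effects ICC(1,1) =
  (MSB - MSW) / (MSB + (k-1) MSW), balanced by truncating every subject to
  the minimum window count; CIs by subject-level bootstrap.  The windows
  are interchangeable repeats, so the one-way form (no rater structure) is
  the appropriate coefficient.
* Cross-validation is always subject-level: stratified 4-fold (by status
  and domain), leave-one-out, cross-institution, or external holdout.
* Group comparisons: one-tailed Wilcoxon rank-sum, Kruskal–Wallis, and
  one-tailed one-sample signed-rank; exact distributions for n <= 10
  without ties, normal approximation with tie correction otherwise;
  all-zero differences return p = 1 under the drop-zeros convention.
  No multiple-testing adjustment is applied (reported p-values are raw).
* Progression: change = (median over the month following the month-6/12
  visit) - (median over the month after baseline); positive = worsening;
  one-tailed signed-rank against zero; a single-night variant replaces the
  medians with each window's first night.

## Attention interpretation

Each 8-s attention step's weight is spread uniformly over its seconds;
seconds are labelled by hypnogram stage or by the argmax relative-power
band (ties toward the lower band), summed per category and renormalized
over the categories present.  PD-vs-control contrasts use one-tailed
rank-sum tests per category.

## The synthetic cohort simulator

The generator emulates the statistical structure the method assumes, not
physiological realism:

* breathing is an amplitude-modulated quasi-sinusoid; the instantaneous
  rate follows an Ornstein–Uhlenbeck process (tau = 60 s, sd 0.015 Hz)
  around a per-subject base rate (0.25 +/- 0.02 Hz);
* disease scales three channels linearly in severity/80: rate-variability
  x(1 + 2.0 s), arousal-event rate 2 + 38 s per hour (8-s rate/amplitude
  bursts placed inside Wake/N1 epochs), amplitude irregularity x(1 + s);
* the hypnogram is a 5-stage Markov chain over 30-s epochs; disease moves
  transition mass toward Wake/N1;
* per-second qEEG is Dirichlet noise (concentration 60) around stage
  templates, with delta suppressed (up to 35%) and beta elevated (up to
  60%) by severity;
* domains differ: wireless traces are low-passed at 0.6 Hz (RF breathing
  is smoother than a belt trace), carry a coloured noise floor, an
  amplitude scale, an interference tone (0.6–0.8 Hz), and attenuated burst
  amplitudes; belt adds only light white noise;
* severity: PD uniform 20–80, controls 0–10; clinician-recorded scores add
  N(0, 2) noise; longitudinal cohorts drift severity at 6 points/year with
  night windows at baseline, month 6 and month 12.

Effect magnitudes are free configuration whose defaults were calibrated
once — on a held-out fold, before freezing — so that desk-scale training
succeeds; the null configuration (`null_config`) zeroes every disease
effect and is the leakage control.  Passing tests therefore show that the
pipeline recovers the *kind* of structure the method assumes when it is
present at learnable strength; they do not certify performance on clinical
recordings, whose effect sizes, artifacts and confounding are far less
cooperative.

## Experiment sizes

The validation experiments (`breathpd.experiments`) run at sizes chosen for
a single CPU: detection uses 40+40 subjects with three 30-min nights each
and 30 training epochs under 4-fold CV (plus a null-cohort rerun); severity
recovery trains one 45-epoch model with w_sev = 2 and tests on an
independent 20+20 cohort; domain invariance uses 16 subjects per
(class x domain) cell with 10-min nights, with qEEG labels on the belt
domain only (as in real acquisitions — and consequential: qEEG supervision
on wireless nights forces broadband, noise-floor-sensitive features that no
adversarial pressure can make domain-invariant); reliability and progression
experiments run on prediction-level simulations (no network), with 100
replicate cohorts for progression power.  Full-length (8-h) nights and
larger cohorts are a matter of configuration, not code.

## Known limitations

* The numpy engine is single-threaded and desk-scale; clinical-scale
  training would use a GPU framework with the same architecture.
* The simulator's disease effects are low-dimensional and mutually
  consistent by construction; real nights contain apnea, movement
  artifacts, medication effects and staging errors that it does not model.
* Subpart severity heads (I–IV) are architectural drop-ins; the bundled
  experiments exercise the total-score head.
* Platt calibration assumes both classes appear in every calibration
  subset; degenerate subsets raise rather than extrapolate.
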