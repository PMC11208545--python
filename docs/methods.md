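# Methods

## Problem setting

Annotated arrhythmia databases are heavily imbalanced: normal beats dominate,
while clinically critical classes such as atrial premature beats make up only
a few percent of the data (the MIT-BIH five-class split used throughout is
N / A / V / L / R: normal, atrial premature, premature ventricular, left and
right bundle-branch block).  Classifiers trained on such data lose precision
and recall exactly on the scarce classes.  `ecggen` addresses this by
synthesizing class-conditioned heartbeats with a conditional, transformer-
based generative adversarial model and by screening the synthetic beats for
actual classification benefit before they are admitted into a training set.

## Preprocessing

**Wavelet denoising.**  Records are decomposed with a fifth-order Daubechies
wavelet (`db5`) to nine levels (details cD9..cD1, approximation cA9),
symmetric boundary extension.  The noise scale is estimated as

    sigma = MAD / 0.6745

with the median absolute deviation taken over *all* detail coefficients
pooled.  Classic VisuShrink estimates sigma from the finest subband (cD1)
only; the pooled estimate is a deliberate choice here, and because coarse
subbands carry signal energy it biases sigma (and hence the threshold)
upward on signal-rich traces.  The universal threshold

    lambda = sigma * sqrt(2 ln N)

uses the full signal length N, and every detail subband is soft-thresholded
(`sign(d) * max(|d| - lambda, 0)`) before reconstruction.  Denoising is
deterministic and leaves sampling rate, length and annotations untouched.

**SNR.**  The denoising report uses SNR = 10 log10(P_signal / P_residual)
with the denoised trace as signal and (input − denoised) as residual.  No
standard definition is canonical for this quantity; this one measures how
much energy the shrinkage removed relative to what it kept, and is the
definition used by `snr_report` and the CLI.

**Segmentation.**  Beats are windows `[r-100, r+200)` around each annotated
R-peak (300 samples at 360 Hz, one full cardiac cycle).  Windows crossing a
record edge are dropped rather than padded, so no synthetic edge artifacts
enter training.  Records are z-scored before cutting (configurable off):
generative training needs a common amplitude scale.  Plain strided
downsampling (every k-th sample, no anti-alias filter) reduces the window to
the model's sequence length; the default interval 3 maps 300 → 100 samples.

## The generative model

Four networks share one trunk design: a multi-scale convolutional stem
(kernels 1, 3, 5; each conv followed by a stride-1, same-padded max pool
that smooths locally without shortening the sequence), additive sinusoidal
positional encoding, pre-norm multi-head self-attention with a residual
connection, and a residual width → 2·width → width feed-forward.  At full
scale the stem lifts 1 → 64 → 128 → 512 channels over a 100-sample axis with
8 attention heads; the desk preset used by the tests and the acceptance
script shrinks this to width 32, 4 heads, batch 32.

- **Encoder** E: beats (B, 100, 1) → latents (B, 100, W).
- **Decoder** D: latents → beats, per-timestep linear head to one channel.
- **Generator** G: per-timestep Gaussian noise (B, 100, W) concatenated with
  a one-hot class block → latents.
- **Discriminator** C: beats concatenated with the one-hot class block →
  time-pooled per-class real/fake logits (B, n_classes); the logit at the
  conditioning class is the adversarial score.

The one-hot condition block is scaled by sqrt(noise_width) before
concatenation.  Without this the single active unit is energetically
negligible against the unit-variance noise channels, and desk-scale
optimization reliably converges to a generator that ignores its condition
(verified by measuring the output's sensitivity to the label); the scaling
makes the condition pathway competitive from the first update.  The
discriminator consumes decoded/real *beats* (not latents), mirroring the
layer plan in which its stem is identical to the encoder's; generator
updates therefore backpropagate through the decoder.

The decoder and discriminator heads are plain linear maps (their output
widths, 1 and n_classes, admit no residual); encoder and generator keep the
residual feed-forward.  Dropout (default 0.1 at full scale, 0 at desk scale)
is applied after the attention and feed-forward sub-blocks during training.

## Training procedure

Training runs in three phases over a fixed epoch budget (default split
35% / 35% / 30%), followed by conditional generation:

1. **Autoencoding.**  E and D minimize mean-squared reconstruction error,
   establishing the reversible high↔low dimensional mapping.
2. **Supervised (conditional-mean regression).**  G's decoded output
   `D(G(z, y))` is regressed onto the class-conditional mean beat of class
   y, with conditioning labels drawn *uniformly over classes* so scarce
   classes receive as much gradient as common ones.  The minimizer of this
   per-sample loss is the class-conditional first moment, i.e. it is
   first-moment matching — but measured in beat space with dense per-sample
   gradients.  Two latent-space alternatives were tried and rejected on
   measurement: batch-level conditional moment matching (conditional moments
   of a class with 1–2 samples per batch are noise) and direct latent-mean
   regression (its achievable residual per latent entry is comparable to the
   between-class latent separation, so the decoded output collapses onto a
   single attractor class even as the latent loss falls).
3. **Adversarial.**  Alternating non-saturating binary cross-entropy updates
   with two generator updates per discriminator update (the 2:1 schedule).
   Three stabilizers matter at this scale: the encoder/decoder are *frozen*
   (letting them keep training moves the latent geometry faster than G can
   track, which detrains conditioning); the discriminator also scores real
   beats under deliberately wrong labels as fakes, so its per-class logits
   enforce label consistency and not just realism; and the Step-2 anchor
   stays in the generator loss with weights
   reconstruction : supervised : adversarial = 10 : 10 : 1 (configurable).
   Reconstruction is logged as an evaluation quantity during this phase.
4. **Generation.**  For each requested class, class-conditioned noise is
   generated, mapped through G and decoded by D; output counts are exact.

All four networks use Adam (learning rate 1e-4 at full scale, 1e-3 desk).
Every source of randomness — initialization, batch order, noise draws,
dropout — flows through one `numpy.random.Generator`; checkpoints serialize
network parameters, optimizer moments and the RNG state, so an interrupted
run resumes bit-identically.

## Evaluation metrics

- **PRD** = 100 · sqrt(Σ(ref−cand)² / Σref²), reported on the percent scale.
- **FD**: the discrete Fréchet distance, computed by the standard dynamic
  program over monotone couplings with |a_i − b_j| as ground distance.  It
  is regression-tested against a brute-force oracle that enumerates all
  couplings for short sequences.
- **RMSE / MAE** as usual.
- Generation reports pair each synthetic beat with the mean real beat of its
  class by default (`pairing="nearest"` is available); no pairing convention
  is canonical for set-to-set beat comparison, and the class mean is the
  most stable reference.
- Classification reports give per-class precision/recall/F1 in percent with
  macro (unweighted) averages and a confusion matrix; a never-predicted
  class takes precision 0.

## Classifier harness and screening

Beats are projected to 16 principal components (PCA fitted on training data
only), then classified by a 1-D residual network: a 3-kernel stem, two
stages of residual blocks (kernels 5 then 3), identity shortcuts with a
1-kernel projection on channel changes, batch normalization, and a dense
head.  Training uses binary cross-entropy on one-hot targets with sigmoid
outputs and an argmax decision rule.  The full preset follows the published
table (64 → 128 → 256 channels, 8 blocks per stage, 3 convs per block,
batch 256, 1e-4, 100 epochs); the desk preset uses 8 → 16 → 32 channels,
2 blocks per stage, 2 convs per block, 1e-3, 30 epochs.

**Screening** retrains the classifier on the real training split plus a
candidate batch of synthetic beats and accepts the batch iff macro F1 on the
real held-out split strictly improves over the baseline trained on real data
alone (same split, same seed).  Screening granularity is the batch, not the
single beat — per-beat retraining is computationally indefensible — with
batch size configurable.  Both baseline and augmented classifiers are always
scored on the same *real* held-out beats; synthetic beats never enter a test
set.

**Augmentation comparisons** (`augmented_report`, `augmented_cv_report`)
follow the same rule.  The CV variant pools predictions over a stratified
K-fold of the real data so that every scarce-class beat is scored exactly
once per repeat: with a 4% minority in a 250-beat fixture, a single 80/20
split holds out only two minority beats, and recall measured on two samples
cannot distinguish synthesis quality from luck.

## Synthetic fixture

The fixture generator emulates an annotated arrhythmia record as a sum of
Gaussian bumps per wave (P, Q, R, S, T) with class-distinct parameters:
atrial premature beats get an early prominent P wave, ventricular beats a
wide high-amplitude QRS without P, the bundle-branch blocks widened or
notched QRS complexes.  Beats are placed at jittered RR intervals
(330 ± 12 samples) with additive Gaussian noise; defaults use 0.05 mV noise,
at which a nearest-template classifier separates the five classes with
≥ 95% accuracy — guaranteeing the fixture carries class signal for
generative and classification experiments.  Classification-difficulty
experiments (imbalance harm, augmentation benefit, screening) raise the
noise to 0.3 mV so that baseline errors exist and improvements are
measurable; a fixture on which the baseline is already perfect could show no
augmentation effect.

What the fixture does *not* emulate: real P/QRS/T asymmetry and patient
variability, rhythm-level phenomena (bigeminy, fibrillation episodes),
baseline wander, electrode artifacts, or multi-lead structure.  Passing
tests therefore demonstrate that the pipeline's machinery works — the
mappings are learnable, conditioning carries signal, augmentation helps a
deliberately impoverished minority class — not that clinical-grade ECG
synthesis is achieved on real recordings.

## Problem sizes used by tests and the acceptance script

Desk-scale conditions, chosen once: 300-beat five-class fixture
(N 120 / A 40 / V 50 / L 50 / R 40), sequence length 100 (interval-3
downsampling), width-32 networks, 30 epochs for the generative study; a
250-beat fixture with a 4% minority (A 10), 24-epoch fits and 3-fold pooled
CV for the five-seed augmentation study; 16k-sample records for denoising.
Smoke tests use length-50 beats and width-16 networks.

## Known limitations

- The discrete Fréchet distance is O(nm) per pair in pure Python; for long
  beats at scale this dominates `generation_report`.
- The supervised anchor targets the class-conditional mean; within-class
  diversity of generated beats comes only from the (gentle) adversarial
  phase and the noise path, so generated sets are less dispersed than real
  ones.
- BCE-on-one-hot (rather than softmax cross-entropy) follows the published
  configuration; it slows early classifier convergence slightly.
- MAD-based sigma over pooled subbands overestimates noise on signal-rich
  records (see Preprocessing); per-record SNR values on real databases
  depend on the unstated SNR convention.
- With fewer than ~10 minority examples the encoder's class-conditional
  moments are themselves noisy; conditioning quality for such classes
  varies across seeds, which is why augmentation claims are made as
  majority votes over seeded repeats.
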