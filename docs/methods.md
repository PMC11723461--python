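# Methods

## Problem setting

Scalp EEG is routinely contaminated by ocular (EOG), muscular (EMG) and
cardiac (ECG) potentials whose amplitude and spectrum overlap the brain
signal. This package implements a single-channel denoiser for 2 s
segments sampled at 512 Hz (1024 samples): a dual-branch hybrid
CNN–Transformer generator trained adversarially against three
least-squares discriminators, together with the semi-simulated
contamination protocol used to build training data and the six-metric
suite used to score recovery quality.

## Contamination model

A contaminated segment is a linear superposition of a clean segment x
and an artifact segment n:

    y = x + λ·n,        SNR = 10·log10( RMS(x) / RMS(λ·n) )  [dB]

λ is solved in closed form, λ = RMS(x)/(RMS(n)·10^(SNR/10)), so the
nominal SNR is realized exactly (tested to 1e-9 dB). The convention
puts the ratio of RMS amplitudes — not powers — inside the logarithm;
a consequence used throughout the tests is that the "do-nothing"
denoiser f(y)=y has time-domain relative error RMS(y−x)/RMS(x) =
10^(−SNR/10), exactly 1 at 0 dB.

Pairs are partitioned 80/10/10 into train/validation/test at the
segment level (disjoint; seeded). Training pairs are mixed at one SNR
each, drawn uniformly from the ten integer levels −7…2 dB (a
continuous-uniform mode is available); every validation/test pair is
mixed once at each of the ten levels, so those partitions are ten times
their pair count. Mixed (EOG+EMG) artifacts are the sample-wise sum of
an EOG and an EMG segment with equal unit weights, rescaled by a single
λ.

## Synthetic data generator

The generators emulate the statistical structure of the public pools
the method is normally trained on, so the pipeline is fully testable
offline:

* **EEG**: 1/f^α background (α drawn in [1, 2]) plus alpha-band
  (8–13 Hz) and theta-band (4–8 Hz) oscillations with random amplitude,
  slow frequency modulation and phase.
* **EMG**: broadband noise with an approximately flat spectrum to
  Nyquist.
* **EOG**: one or two well-separated smooth blink deflections (Gaussian
  bumps, ≈0.2 s wide, 4–6× the drift amplitude) over slow drift,
  band-limited to 0.5–5 Hz.
* **ECG**: a quasi-periodic QRS-like biphasic spike train at 50–90 bpm
  with ~5% inter-beat jitter and a small T wave; power concentrated
  below 20 Hz.

Band-limiting uses frequency-domain masking with raised-cosine rolloffs
rather than IIR filters so output is bit-reproducible across platforms.
All generators emit zero-mean, unit-variance segments: absolute
amplitude is irrelevant because λ absorbs scale. What these emulations
do **not** capture: non-stationarity across segments from a single
subject, electrode drift and line noise, the true cross-correlation
between concurrent EEG and EOG, and the waveform diversity of real
muscle activity. Passing tests therefore demonstrate that the machinery
(mixing, training dynamics, metrics) behaves correctly, not that the
trained desk-scale model transfers to clinical recordings.

## Generator

Input is a standardized 1024-sample segment. Two structurally identical
branches learn, respectively, the clean-EEG distribution (output Y1)
and the additive contamination (output Y2). Two gating networks (two
fully connected layers, 1024→512→1024, tanh output) produce masks in
(−1, 1), and the fused prediction is

    Ypre = mask1 ⊙ Y1 + mask2 ⊙ (Xraw − Y2).

Each branch is:

* **Preprocessing** — two k=3 convolutions to 32 channels, then average
  pooling (kernel 2, stride 2): 512 tokens.
* **Encoder** — five blocks with channel widths 64, 128, 256, 512, 1024.
  Each block runs a CNN stream (conv k=3 stride 2 + conv k=3, each with
  BatchNorm and LeakyReLU 0.2) in parallel with a Local–Global
  Transformer Block: average-pool ×2, then partition-local multi-head
  self-attention over 8 contiguous chunks, a residual feedforward,
  global self-attention over all tokens, a second feedforward, and a
  conv/BN/LReLU tail projecting to the block width. Streams exchange no
  information until a single fusion layer (channel concat → 1×1 conv →
  BN) after the last block.
* **Decoder** — two convolutions narrowing the channels, then one fully
  connected layer mapping the flattened latent back to 1024 samples.

Design choices made where the architecture was genuinely open:

* **Temporal downsampling**: each encoder block halves the token count
  (512→16 over five blocks). Only the channel schedule is prescribed;
  halving keeps attention cost bounded, makes the flatten→FC decoder
  small, and mirrors the discriminator's stride-2 ladder. The 8 local
  partitions divide the token count at every stage (16/8 = 2 at the
  last).
* **Attention**: 4 heads per stage, residual connections around each
  attention and feedforward stage, no layer normalization (only the
  BatchNorm stages the architecture prescribes). With the output
  projections and second feedforward layers zeroed, the attention stack
  is exactly the identity — a tested property.
* **Gate initialization**: the noise-branch gate's output bias starts at
  +1.5 (mask2 ≈ 0.9) and the clean-branch gate at 0, so optimization
  starts near the algebraically correct route Ypre ≈ Xraw − Y2 and
  opens the clean branch as it becomes useful. With few updates this
  matters: the subtraction route passes full-bandwidth signal around
  the encoder bottleneck, which the correlation metrics reward.
* **Bias-free convolutions before BatchNorm**: the normalization cancels
  a per-channel bias exactly, so those biases would be provably dead
  parameters.
* **width_scale** divides every channel width uniformly (8 → widths
  8…128) for desk-scale runs; the architecture is otherwise unchanged.

Ablation switches (clean branch only, noise branch only, no transformer
stream, plain full-sequence self-attention) are configuration flags on
the same code path.

## Discriminators and losses

Three discriminators with identical architecture but independent
weights score: D1 — branch-1 output vs real clean EEG; D2 — branch-2
output vs the true contamination λ·n; D3 — the fused output vs real
clean EEG. Each is eight conv(k=3, stride 2, pad 1)/BN/LReLU stages
with channels 64, 64, 128, 128, 256, 256, 512, 512 (1024 → 4 samples),
then a fully connected head to one scalar. No sigmoid on the score
(least-squares GAN); a flag restores one.

Generator losses, per output k ∈ {1, 2, 3}:

    Loss_k = L_mse + λ1·L_feat + λ2·L_adv,      Ltotal = ΣLoss_k

with L_mse the batch-mean squared error against the branch target
(branch 2 regresses on λ·n — the scaled contamination, since that is
what Xraw − Y2 must cancel), L_feat the MSE between discriminator
feature maps of prediction and target (default: all 8 stages, per-stage
MSE averaged; a single stage is selectable), and L_adv =
mean((D(pred) − 1)²). Discriminators minimize
mean(½D(fake)² + ½(D(real) − 1)²). λ1 = λ2 = 0.01 by default (no values
are prescribed anywhere; the regression term should dominate at desk
scale), both configurable.

## Training procedure

Alternating updates: each step trains D1, D2, D3 on their own losses
with the generator's outputs detached, then the generator on Ltotal
with the discriminators frozen in eval mode. Adam with (β1, β2) =
(0.5, 0.9) for the generator and (0.9, 0.999) for the discriminators;
batch size 40; up to 1000 epochs. After every epoch the validation MSE
of the fused output is computed; training stops once it has worsened
more than C consecutive epochs (default patience C = 5, inner
iteration count K = 1), and the best-validation weights are restored —
not the last.

Two learning rates are in circulation for this architecture (1e-3 and
1e-4); the package defaults to 1e-4 and uses 1e-3 for the short
desk-scale runs below, where only ~150 generator updates occur and the
smaller rate barely moves a fresh model.

At test time segments are standardized by their own standard deviation,
passed through the generator, and the fused output is rescaled back.
Per-pair standardization (mixture, clean target and noise share the
mixture's factor) bounds network inputs; the factor is stored so the
transform inverts exactly.

## Numerical and implementation notes

* The network runs on a compact reverse-mode autodiff engine written in
  numpy inside the package (float32 parameters; conv1d via im2col +
  GEMM). Gradients of every primitive are verified against central
  finite differences in float64. Metrics are computed in float64.
* All randomness flows through seeded `numpy.random.default_rng`
  generators; a fixed seed reproduces training logs bit-for-bit in a
  fixed thread configuration.
* PSDs use a single rectangular-window periodogram over the full
  segment (one-sided, density scaling), chosen so the spectral error
  metric is bit-reproducible; the Parseval identity is tested.
* The 1-D SSIM is computed globally from whole-segment means, variances
  and covariance with C1 = C2 = 1e-4 (its plateau form); a sliding-
  window variant exists but is off by default.
* Mutual information uses a plug-in 2-D histogram with equal-width bins
  over each signal's observed range, natural log. The default is 12
  bins per axis: the plug-in estimator's positive bias is roughly
  (K−1)²/(2N) nats, so 64 bins would contribute ≈0.9 nats of spurious
  MI at N = 1024 while 12 bins keep the bias near 0.06, letting
  independent signals score ≈0 as they should. The bin count is
  configurable.
* η = (1 − (1−CC)/(1−CCb))·100 is the implemented reading of the
  percentage-reduction metric: it is the only affine arrangement of CC
  and CCb under which perfect recovery scores 100 and doing nothing
  scores 0, and it reproduces jointly reported CC/η value pairs for
  plausible CCb.
* Degenerate inputs raise typed errors: zero-variance segments cannot
  be standardized or denoised, zero-RMS components cannot be mixed to a
  target SNR, and η is undefined when the "contaminated" input already
  correlates perfectly with the clean signal.

## Desk-scale study conditions

Full-width training on real pools is a GPU-scale undertaking; the
repository's end-to-end checks instead run a width_scale=8 model on 200
synthetic EOG-contaminated training pairs (batch 40, 30 epochs, lr
1e-3, fixed seed), with 25 held-out artifact segments mixed at each of
the ten SNR levels for evaluation. Under these conditions the trained
model must beat the do-nothing baseline on both mean correlation and
mean time-domain error, and reach RRMSE_t < 0.9 at 0 dB. The same run,
repeated with the same seed, must reproduce its training log
byte-for-byte. `scripts/acceptance.py` re-runs exactly this pipeline
from scratch and writes the measured quantities as JSON.

## Known limitations

* The desk-scale model is a faithful miniature, not the full-width
  network; its absolute scores are far from what GPU-scale training on
  real pools reports, and no claim is made otherwise.
* Single-channel only; no cross-channel information, no streaming
  inference.
* The adversarial terms are kept small by default; with λ2 ≫ λ1, L_mse
  the training dynamics of the full-scale model may need the usual GAN
  stabilization care that is out of scope here.
* The synthetic generators are spectral emulations (see above); results
  on them bound correctness of the machinery, not clinical performance.
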