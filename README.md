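# eegdenoise

Removal of physiological artifacts — ocular (EOG), muscular (EMG),
cardiac (ECG) and mixed (EOG+EMG) — from single-channel EEG segments
with a dual-branch hybrid CNN–Transformer generative adversarial
network, plus the semi-simulated contamination protocol that builds its
training data and the six-metric suite that scores it. Written for
researchers in neurophysiological signal processing who want a fully
seeded, dependency-light (numpy/scipy) reference implementation that
trains and evaluates end-to-end on a laptop.

## The model

A contaminated 2 s segment (1024 samples at 512 Hz) is synthesized by
linear mixing at a controlled signal-to-noise ratio:

    y = x + λ·n,        SNR = 10·log10( RMS(x) / RMS(λ·n) )  [dB]

with λ solved in closed form so the nominal SNR is exact. The denoiser
is a generator G with two encoder–decoder branches — one predicting the
clean signal Y1, one the contamination Y2 — fused by tanh gating masks:

    Ypre = mask1 ⊙ Y1 + mask2 ⊙ (Xraw − Y2)

Each branch runs a preprocessing stage (two 1-D convolutions + average
pooling), five encoding blocks pairing a CNN stream with a Local–Global
Transformer Block (partition-local self-attention over 8 chunks, then
global self-attention, both residual) at channel widths 64…1024, and a
convolutional + fully connected decoder. Three least-squares
discriminators (8 conv/BN/LReLU stages, channels 64…512, stride 2)
score Y1, Y2 and Ypre against their references; the generator minimizes

    Ltotal = Σ_k ( L_mse + λ1·L_feat + λ2·L_adv )_k ,   k = 1, 2, 3

with feature losses taken from the discriminators' intermediate maps.
Training alternates discriminator and generator Adam updates with early
stopping on validation MSE. Quality is reported as RRMSE_t, RRMSE_f
(periodogram domain), Pearson CC (+p-value), percentage artifact
reduction η = (1 − (1−CC)/(1−CCb))·100, a global 1-D SSIM, and mutual
information. See `docs/methods.md` for every formula, default and
design decision.

The network runs on a small numpy reverse-mode autodiff engine included
in the package (`eegdenoise.autodiff`); there is no deep-learning
framework dependency, and everything is reproducible bit-for-bit under
a fixed seed.

## Worked example

```python
import eegdenoise as ed
from eegdenoise.training import build_models, fit, evaluate, evaluate_with

# synthetic pools: clean EEG-like and ocular-artifact-like segments
eeg = ed.gen_eeg(ed.GenSpec(n_segments=250, seed=7))
eog = ed.gen_eog(ed.GenSpec(n_segments=250, seed=8))

# 80/10/10 split; train pairs mixed at one SNR in -7..2 dB,
# val/test pairs mixed once at every one of the ten levels
splits = ed.build_splits(eeg, eog, ed.SplitSpec(seed=7))

models = build_models(ed.GeneratorConfig(width_scale=8, seed=7))
cfg = ed.TrainConfig(batch_size=40, max_epochs=30, early_stop_C=30,
                     lr_gen=1e-3, lr_disc=1e-3, seed=7)
result = fit(splits.train, splits.val, models, cfg)

trained = evaluate(models, splits.test).summary.iloc[-1]
baseline = evaluate_with(lambda y: y, splits.test).summary.iloc[-1]
print(f"denoised:     RRMSEt {trained['rrmse_t']:.4f}  CC {trained['cc']:.4f}")
print(f"contaminated: RRMSEt {baseline['rrmse_t']:.4f}  CC {baseline['cc']:.4f}")
```

Output of this exact script (one CPU, a few minutes):

```
denoised:     RRMSEt 0.8881  CC 0.6404
contaminated: RRMSEt 2.1931  CC 0.5259
```

Reading: averaged over the ten SNR levels, the trained desk-scale model
cuts the relative time-domain error of the contaminated input by more
than half (the baseline value 2.19 is exactly the analytic mean of
10^(−SNR/10) over −7…2 dB) and raises the correlation with the hidden
clean signal above the do-nothing baseline. At 0 dB the model reaches
RRMSE_t ≈ 0.65 against the analytic baseline of exactly 1.0. A
width_scale=8 model trained for 150 updates is a miniature — full-width
GPU training on real pools is where the method's headline numbers come
from — but every mechanism (mixing, losses, alternating updates, early
stopping, metrics) is the real thing.

The same pipeline is scriptable from the shell:

```bash
eegdenoise simulate --type eeg --n 250 --seed 7 --out eeg
eegdenoise simulate --type eog --n 250 --seed 8 --out eog
eegdenoise mix --eeg eeg --artifact eog --type eog --seed 7 --out data/
eegdenoise train --config cfg.yaml --data data/ --out run/
eegdenoise evaluate --ckpt run/checkpoint.npz --test data/ --report report.csv
```

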