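# ppgid — PPG-based biometric identification

Photoplethysmography (PPG) measures blood-volume changes optically; the
shape of each pulse — systolic peak, dicrotic notch, diastolic peak — is
stable within a person and varies between people, which makes the waveform
usable as a biometric. `ppgid` implements a complete identification
pipeline at desk scale, for researchers who want to study or extend this
kind of system without sensor hardware or access to a subject cohort:

1. **Synthetic cohort generation** — each subject is a draw of beat-template
   parameters (heart period, landmark positions/amplitudes, baseline,
   timing jitter); signals are jittered beat trains plus Gaussian sensor
   noise, quantized to 18-bit ADC counts in [0, 262143]. Defaults: 40
   subjects × 80 signals × 300 samples.
2. **Preprocessing** — Savitzky–Golay smoothing (sliding least-squares
   polynomial fits, window 11, order 3) and min–max normalization
   x′ = (x − min x)/(max x − min x) to [0, 1].
3. **Gram-matrix imaging** — each normalized signal s ∈ ℝᴺ becomes the
   rank-1 Gramian G = s sᵀ, an N×N image of pairwise sample products
   (G_{mn} = s_m s_n); the literal cross-signal form G_{ij} = ⟨s_i, s_j⟩ is
   kept for similarity analysis. Images are rescaled and bilinearly
   resampled to the classifier's input side.
4. **Train-only augmentation** — horizontal flip with singular-value
   perturbation (σ_i ← σ_i(1 + ε), ε ~ N(0, σ)), principal-component
   perturbation, and bounded random rotation (≤ 90°).
5. **Classifier** — a compact CNN+LSTM written in NumPy with hand-derived
   backpropagation: a strided stem convolution, inverted-residual (MBConv)
   blocks — pointwise expand → 3×3 depthwise → squeeze-and-excitation gate
   → pointwise project, with identity skip when shapes match — Swish
   activations, then the final feature map read row-by-row as a sequence
   into an LSTM and a softmax head.
6. **Evaluation and streaming** — stratified 80/20 split, three
   hyperparameter presets (SGD/Adam/RMSprop grid), early stopping on
   validation loss (patience 10), confusion matrix with per-class and
   macro/weighted precision/recall/F1, and a replayed-stream identification
   loop with a stabilization discard.

## Worked example

The standing end-to-end check trains the tiny model preset on a low-noise
synthetic cohort of 8 subjects × 40 signals (80/20 split, Adam at 1e-3,
batch 32, up to 25 epochs):

```python
from ppgid.pipeline import parameter_recovery_run

res = parameter_recovery_run(seed=1)
rep = res.report
print(f"test accuracy      : {rep.accuracy:.3f}")
print(f"macro F1           : {rep.macro_f1:.3f}")
print(f"epochs run / best  : {res.history.stopped_epoch} / {res.history.best_epoch}")
print(f"model parameters   : {res.model.parameter_count()}")
print("confusion diagonal :", rep.confusion.diagonal().tolist())
```

prints

```
test accuracy      : 1.000
macro F1           : 1.000
epochs run / best  : 25 / 25
model parameters   : 34244
confusion diagonal : [8, 8, 8, 8, 8, 8, 8, 8]
```

i.e. all 64 held-out signals (8 per subject) are assigned to the correct
subject by a 34k-parameter model — the synthetic identities are cleanly
separable at this noise level.

The same pipeline is scriptable from the shell:

```bash
ppgid generate --subjects 8 --per-subject 40 --seed 1 --out data/
ppgid train --data data/ --variant filtered --seed 1 --out model.npz
ppgid identify --model model.npz --simulate 0 --stabilize 25 --window 300
```

The `identify` subcommand replays a stream (a CSV of ADC counts, or a live
synthetic generator), discards the 25-second stabilization period, captures
a 300-sample window, and prints the predicted subject with its softmax
confidence and per-stage timings.

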