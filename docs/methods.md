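# Methods

## The synthetic cohort

No public PPG identification corpus matches the acquisition design this
package targets (40 subjects, 80 signals each, 300 samples per signal,
18-bit ADC counts), so the cohort is generated. A subject is a fixed draw
of beat-template parameters — the biometric identity:

| parameter | range (uniform) | units |
|---|---|---|
| heart period | 0.65 – 1.10 | s |
| systolic amplitude | 0.75 – 1.00 | relative |
| systolic position | 0.20 – 0.30 | beat fraction |
| systolic width | 0.040 – 0.070 | s |
| dicrotic amplitude | 0.12 – 0.32 | relative |
| dicrotic position | 0.44 – 0.54 | beat fraction |
| diastolic amplitude | 0.25 – 0.50 | relative |
| diastolic position | 0.64 – 0.78 | beat fraction |
| baseline level | 50 000 – 120 000 | ADC counts |

One beat is the sum of three Gaussian bumps at the systolic, dicrotic and
diastolic positions (the diastolic bump 1.2× wider). This is the simplest
parametric family that reproduces the canonical landmarks: a unimodal rise
to a global systolic maximum, a local minimum (the dicrotic notch) after
systole, and a secondary diastolic peak. The ranges guarantee the landmark
ordering and amplitude dominance invariants by construction, and were
chosen wide enough that default sensor noise does not erase identity.

A signal concatenates beats whose periods are jittered per beat by
N(0, 0.01 s) (truncated to the physiological [0.5, 1.5] s range), scales by
100 000 counts per unit relative amplitude, offsets by the subject
baseline, adds i.i.d. Gaussian noise (default SD 800 counts), clips to
[0, 2¹⁸ − 1] and rounds. The sampling rate defaults to 50 Hz so that a
300-sample signal spans ≈ 6 s ≈ 5–8 beats; the rate is configurable since
acquisition hardware typically logs far below its ADC's maximum rate.

Randomness is one `SeedSequence` per dataset, spawned per subject, so the
cohort is bit-reproducible and adding subjects never perturbs existing
ones.

**What this emulates and what it does not.** The generator reproduces
inter-subject morphology differences, intra-subject beat-to-beat timing
jitter, additive sensor noise and ADC quantization. It does not model
motion artifacts, baseline wander from respiration, contact-pressure
changes, arrhythmia, or day-to-day physiological drift — the main reasons
real PPG biometrics degrade. A model that separates this cohort perfectly
is therefore evidence the pipeline works end to end, not evidence of
field-grade identification accuracy.

## Preprocessing

Savitzky–Golay smoothing fits a polynomial of order 3 to each sliding
window of 11 samples by linear least squares and keeps its value at the
window center; for evenly spaced samples this is a fixed convolution
(delegated to `scipy.signal.savgol_filter`). Edges evaluate the boundary
window's polynomial at the edge offsets (`mode="interp"`), which preserves
signal length without fabricating periodicity. Window/order are exposed in
`SavGolParams`; 11/3 is a common choice for pulse smoothing at tens of Hz.

Min–max normalization maps to [0, 1]. The pipeline order is fixed —
filter, then normalize — so the [0, 1] contract holds at the boundary the
Gram stage consumes. A constant signal raises `DegenerateSignalError`
rather than silently producing zeros: a flat window carries no identity and
must surface as an error, and the check runs *before* smoothing because the
filter's floating-point round-off can make an exactly constant input
minutely non-constant.

Three dataset variants exist: `raw` (normalize only), `filtered`
(smooth + normalize) and `mixed` (the union — every source signal
contributes both records, so 3200 sources yield 6400 records).

## Gram-matrix imaging

The per-signal form is G = s sᵀ for one normalized signal s: symmetric,
positive semidefinite, rank ≤ 1, diagonal s_m², all entries in [0, 1]. It
is the sample-pairwise restriction of the general Gram construction
G_ij = ⟨s_i, s_j⟩, which is kept as `cross_gram` for cross-signal
similarity analysis. Whether a Gramian image of a single signal should be
the outer product, a Gramian angular field, or a windowed variant is a
genuinely open design choice; the outer product was chosen because it is
the only form that yields one N×N image per signal with no extra
parameters. Angular-field variants are explicitly out of scope.

Rendering min–max rescales intensities (a monotone map — argmax and
ordering preserved) and bilinearly resamples to the classifier side.
Constant matrices render as all-zero intensity by convention. The default
render side is 224 (the conventional input side for this CNN family); all
desk-scale training uses 32, which keeps a 300×300 Gramian's structure
while making CPU training fast.

## Augmentation

Applied to the training split only, enforced with an explicit guard.
The flip chain is horizontal flip followed by singular-value perturbation
(each σ_i scaled by 1 + ε, ε ~ N(0, 0.05), clipped at zero — a controlled,
structure-preserving distortion since the Frobenius change is exactly
√Σ(σ_iε_i)²). PCA perturbation scales row scores on the top-k principal
components and re-adds the discarded residual, so σ = 0 is lossless for any
k. Rotation draws an angle uniformly in [−90°, +90°], interpolates
bilinearly and fills with zeros (zero = "no similarity"; reflection fill
would fabricate structure); exact multiples of 90° are routed through an
index permutation so no interpolation error appears at right angles.
Default expansion is 10 copies per image (≈ 11× the originals). Each copy
records its operator chain and source in the dataset manifest.

## The classifier

Written in NumPy with hand-derived reverse-mode gradients; layout NHWC.

- **Convolution** (same padding, centered odd kernel, output side
  ⌈input/stride⌉): y(i,j,k) = Σ_{m,n,c} x(is+m−⌊M/2⌋, js+n−⌊N/2⌋, c)·Q(m,n,c,k) + B(k).
  The vectorized implementation is tested against a literal quadruple-loop
  oracle at 1e−10.
- **MBConv** (inverted residual): 1×1 expand (factor t) → BN → act → 3×3
  depthwise (stride 1 or 2) → BN → act → squeeze-and-excitation →
  1×1 project → BN, with x added back when stride 1 and channels match.
- **Squeeze-and-excitation**: z_c = mean over (h,w) of x(·,·,c);
  gate = sigmoid(W₂·act(W₁z + b₁) + b₂); output x·gate per channel, with
  reduction width max(1, C/4).
- **Swish**: v·sigmoid(v) — default hidden activation; ReLU and LeakyReLU
  selectable via the hyperparameter presets. Softmax is always the output.
- **Batch normalization** after each convolution, before activation —
  standard for this block family; running statistics are used at inference.
- **Sequence head**: the final H′×W′×C′ feature map is read as H′ time
  steps of W′·C′ features (row-major); a single-layer LSTM (forget bias 1)
  consumes the sequence; its final hidden state feeds a dense softmax over
  the subjects. Reading rows as time steps is a deterministic,
  shape-preserving choice for turning one image into a sequence; per-frame
  video sequencing is out of scope.

Presets: `tiny` — 32-px input, stem (stride 2) + 3 MBConv blocks
(one stride 2), 8×8×24 feature map, LSTM 32, ~34k parameters at 8 classes;
`paper_scale` — 224-px input, the published B0-family 7-stage layout
(66 weighted layers counting each convolution, SE module, the LSTM and the
head), provided for construction and inspection — training it on CPU is
not practical and no pretrained weights are used.

## Training and evaluation

Stratified per-subject 80/20 split (every class present on both sides;
per-subject train count = round(0.8 × count)). Three presets mirror the
ablation grid: (16, default-Swish, SGD, 0.01), (32, ReLU, Adam, 0.001),
(64, LeakyReLU, RMSprop, 0.0001). Loss is categorical cross-entropy
(implied by the softmax head). A 10 % validation fraction is carved from
the training data after augmentation; early stopping halts after 10 epochs
without validation-loss improvement (strict `<`) and restores the
best-validation weights, within a 25-epoch budget. With a monotonically
worsening validation loss this stops at epoch 11 exactly (best epoch 1 +
10 stale epochs).

Metrics are computed from first principles: precision TP/(TP+FP), recall
TP/(TP+FN), F1 their harmonic mean, macro = unweighted class mean,
weighted = support-weighted mean; a class with zero support or zero
predictions scores 0 with a logged warning. scikit-learn's implementations
serve as an independent cross-check in the test suite only.

The standing end-to-end check (`parameter_recovery_run`) uses 8 subjects ×
40 signals at noise SD 300 counts, image side 32, the Adam preset, and
asserts median test accuracy ≥ 0.95 over three seeds. These sizes keep a
full run under a minute per seed on one CPU while leaving ~64 held-out
windows per run.

## Streaming identification

A `StreamSource` replays a CSV of ADC counts or a live synthetic generator
in place of serial-port hardware. A session discards exactly
round(stabilization × rate) samples (default 25 s — sensors need a warm-up
before the waveform settles), captures a 300-sample window, and runs the
identical offline code path: preprocess → Gram → render → forward pass.
Offline/online probability vectors are therefore equal by construction,
and the equality is asserted in tests rather than assumed. Each result
carries per-stage wall-clock timings; no latency claim is made beyond what
a run reports. Repeated windows within a session resume from the live
stream position (the restart-button analogue). A voting scheme over
multiple windows is a natural extension point and is not implemented.

## Known limitations

- The synthetic cohort's separability is optimistic; see above.
- `paper_scale` is provided structurally; all quantitative results use
  `tiny`.
- Augmentation operators act on rendered rasters, not on raw signals;
  signal-domain augmentation (time warping, amplitude scaling) is not
  implemented.
- The LSTM sees a deterministic row sequence of one image; it cannot model
  across-window temporal context.
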