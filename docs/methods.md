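# Methods

`leadrecon` reconstructs the remaining 11 leads of a standard 12-lead ECG
from a single Lead I strip plus discretized clinical metadata, and attaches
a Monte Carlo-dropout reliability map to every reconstruction. This note
describes the models, the synthetic data they are exercised on, the
numerical choices, and what the package's tests do and do not demonstrate.

## Reconstruction task and preprocessing

The unit of work is a 10-s, 500-Hz, 12-lead record. Signals are decimated
to 100 Hz by keeping every 5th sample starting at index 0 — deliberately
with no anti-aliasing filter, because the intended inputs are pre-denoised
signals whose QRS sharpness the filter would smear. A centered 512-sample
window (5.12 s; start index `floor((T-512)/2)`, shared by all leads) forms
the model input (Lead I, `1 x 512`) and target (leads II, III, aVR, aVL,
aVF, V1–V6 in that fixed order, `11 x 512`), all in mV.

Five metadata fields accompany each record: frontal QRS axis (RAxis),
frontal T axis (TAxis), ventricular rate, QRS count per 10 s, and QRS
duration. Rate and count are linked by the exact conversion
`rate = 6 x count` for a 10-s strip. Each field is discretized with
guideline thresholds:

| feature            | categories (in one-hot order) | thresholds |
|--------------------|-------------------------------|------------|
| RAxis / TAxis      | Normal, Left, Right, Extreme  | −30°≤θ≤90°; −90°<θ<−30°; 90°<θ≤180°; −180°<θ≤−90° |
| QRS duration       | Normal, Prolonged             | <120 ms; ≥120 ms |
| Ventricular rate   | Bradycardia, Normal, Tachycardia | <60; 60–100; >100 bpm |
| QRS count          | Low, Normal, High             | <10; 10–16; ≥17 per 10 s |

Boundary conventions: 60 and 100 bpm are Normal; 10 and 16 counts are
Normal; 120 ms is Prolonged. The concatenated one-hot vector (feature
order RAxis, TAxis, QRSDuration, VentricularRate, QRSCount) has dimension
D = 4+4+2+3+3 = 16 for the full set; any non-empty subset of features can
be selected, supporting single-feature and pairwise conditions. The axes
cannot be measured from Lead I alone (a frontal axis needs two leads), so
axis fields are taken from the metadata sidecar for real data and from
ground truth for synthetic data; `estimate_metadata_from_lead1` recovers
only rate, count and an approximate QRS width (envelope above 25% of the
R amplitude) from the waveform itself.

Datasets are split 70/15/15 at the record level (one record per subject,
so no subject leakage), with sizes `floor(0.70 n)`, `floor(0.15 n)` and
the remainder.

## Models

Three architectures share the same input/output contract and are
implemented in a small numpy layer library with hand-written backprop
(`leadrecon.nn`), whose gradients are verified against central differences
in the test suite:

* **Dual-branch CNN–BiLSTM (the primary model).** Time branch: two 1-D
  convolutions (32 filters, kernel 5, ReLU) over the `1 x 512` input,
  then a bidirectional LSTM (512 units per direction by default) producing
  per-time-step features, then dropout (rate 0.2). Feature branch: three
  fully connected ReLU layers (width 32) on the D-vector. Fusion is late:
  the feature-branch output is broadcast along the 512 time steps and
  concatenated with the BiLSTM features, followed by a second dropout, one
  time-distributed hidden layer (width 256, ReLU) and an 11-unit linear
  output per time step. With D = 0 the feature branch is absent and the
  model degenerates to the time-series-only variant.
* **Early-fusion baseline.** The identical backbone, but the metadata
  vector is repeated along time and concatenated with the waveform at the
  input (`(D+1) x 512`); no feature branch.
* **1-D U-Net baseline.** Depth-3 encoder–decoder (16/32/64 filters,
  kernel 5, max-pool/nearest-upsample by 2, skip connections, 128-filter
  bottleneck with dropout) over the same channel-repeated input.

Choices that were genuinely open: the fully connected widths of the
feature branch (3 × 32) and fusion head (one layer, 256) are not forced by
the architecture sketch and are configurable; fusion is per-time-step
(sequence-to-sequence) rather than on a pooled representation, because the
output must remain temporally aligned at 512 steps; the U-Net scale is a
faithful small configuration of the usual biosignal design.

Training minimizes MSE in raw mV (no normalization, so reported RMSE is in
mV) with Adam (lr 0.001), batch 32, per-epoch shuffling, for 100 epochs by
default. Validation runs every 20 epochs *and always at the final epoch*
(otherwise short runs would never validate); the parameters with the
lowest validation loss are retained, and reloading a checkpoint reproduces
that loss to float tolerance. All randomness (initialization, shuffling,
dropout) derives from a single config seed; identical configs give
identical histories.

Numerical choices: parameters and activations are float32 (signals span
~1e-2 to 2 mV, far from float32 limits; this halves training time), with a
module-wide switch to float64 used by the gradient-check tests. LSTM
forget-gate biases start at 1; other weights are Glorot-uniform.

## Monte Carlo-dropout uncertainty

The two dropout layers — after the BiLSTM block and after the fusion
concatenation, both rate 0.2 — remain active at inference; N stochastic
passes (default 1000; the bundled experiments use 100) give per-time-point
statistics:

* σ(t): population standard deviation over passes (divisor N, matching the
  defining formula, not the N−1 sample estimator);
* σ_norm(t) = σ(t) / max_t σ(t), per lead and per record, in [0, 1]
  (identically zero when σ is identically zero);
* relative error e(t) = |y_pred − y_true| / (|y_true| + ε), with
  ε = 1e-3 mV by default (the stability constant is not dictated by
  anything physical; 1e-3 keeps e bounded at zero crossings while leaving
  near-zero-reference points clearly amplified). A signed variant is
  available by flag.

Reliability analysis pools all (record × time) points per lead and reports
the Pearson correlation between σ_norm and e, plus mean ± SD of e per
σ_norm quartile (Q1 lowest; quartile boundaries by stable argsort, so ties
resolve deterministically). A per-record-then-average correlation variant
exists behind a flag.

**Known limitation.** On the synthetic data, σ_norm correlates clearly
with the *absolute* error (pooled r ≈ 0.3–0.5) but not with the *relative*
error: σ_norm and |y_true| are strongly coupled (uncertainty peaks inside
the QRS) while e, by construction, is largest where |y_true| is smallest,
so the pooled σ_norm–e correlation comes out near zero or negative and the
top σ_norm quartile does not show the largest mean e. A positive
relative-error correlation requires a substantial population of points
where the reference is near zero but the prediction is large and uncertain
— beats reconstructed at wrong positions or with wrong morphology, as in
clinically irregular recordings. The generator below intentionally
produces regular, periodic records (see its contract), so this regime is
out of reach of the synthetic testbed; the package reports the correlation
it actually measures.

## Synthetic 12-lead generator

Each record derives from a 3-component pseudo-dipole `(dx, dy, dz)`. A
beat is five Gaussian bumps (P, Q, R, S, T) with per-wave center,
amplitude and width; the QRS bumps point along the frontal axis θ_R, the
T bump along θ_T, and each wave carries a fixed anterior–posterior weight
into dz. QRS duration d maps to the QRS geometry as Q/S centers at
∓0.22 d and Q/R/S sigmas 0.11 d. Beats repeat at the target heart rate
with multiplicative RR jitter (Gaussian, truncated at ±3 SD), the first
beat at RR/2 so a 72-bpm, 10-s record contains exactly 12 beats. White
noise (default 0.01 mV) and an optional baseline-wander sine are injected
at the *dipole* level, never per lead.

Limb leads: Lead I is the projection onto 0°, Lead II onto 60° (hexaxial
convention, angles clockwise in the frontal plane); III = II − I,
aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2 are computed from the
identities, which therefore hold exactly (≤1e-9 mV) on every record,
noisy or not. Chest leads V1–V6 are a fixed full-rank 6×3 mixture of
(dx, dy, dz), graded from right-sided (V1, dominated by −dz) to left-sided
(V6, dominated by dx).

Why this makes metadata informative: Lead I sees only
`dx = m(t) cos θ`, so the frontal axis — hence the sign and scale of dy,
which the limb and chest leads need — is ambiguous from the waveform
alone. The axis categories resolve that ambiguity, which is exactly the
mechanism by which metadata improves reconstruction in this package's
experiments (held-out mean R improves by ≈ +0.05 with all features at the
bundled experiment scale).

The population sampler draws axis categories with probabilities
0.55/0.20/0.15/0.10 (Normal/Left/Right/Extreme) and uniform angles within
the category, heart rates in windows that land each count category safely
(42–54, 63–93, 105–125 bpm), and QRS durations 70–110 ms (75%) or
120–150 ms (25%) — an arrhythmia-database-like skew that still puts mass
on every category. A stratified sampler round-robins every category of
every feature for coverage tests. Ground-truth metadata are emitted with
each record: QRSCount is the number of placed beats, VentricularRate is
6 × QRSCount, axes and QRS duration are the generating parameters.

What the generator does *not* emulate: pathological morphologies (bundle
branch block, AF fibrillatory waves), ectopic or skipped beats, electrode
artifacts, inter-lead noise, and any irregularity that would decouple beat
positions from the Lead I waveform. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that metadata fusion helps
when chest-lead morphology depends on quantities invisible to Lead I; they
do not demonstrate clinical-grade reconstruction on real ECGs.

## Evaluation

Fidelity metrics per record and lead: Pearson R, RMSE (mV), and a 1-D
SSIM (sliding Gaussian window, 11 samples, sigma 1.5, stabilizers
C1 = (0.01 L)², C2 = (0.03 L)² with L the reference's per-record-lead data
range; filter-weighted covariances, cross-checked against a standard image
SSIM implementation). Records are aggregated as mean ± SD of per-record,
lead-averaged values.

Segment-wise analysis detects R peaks on the reference Lead II with a
derivative-energy detector (5–15 Hz band-pass, squared derivative, 150-ms
moving integration, adaptive threshold at 30% of the 98th percentile,
200-ms refractory period, refinement to the local absolute maximum of the
raw signal), then scores fixed windows relative to each R peak —
P [−240, −100) ms, QRS [−60, +60] ms, ST (+60, +160] ms, T (+160, +420] ms
at 100 Hz; configurable — by concatenating the samples of all complete
beats per lead, computing one R per lead and segment, and averaging over
leads. Beats whose windows overflow the record are skipped.

Paired model comparisons use the Wilcoxon signed-rank test for R and SSIM,
the paired t-test for RMSE, and Holm step-down correction across the
declared metric family at α = 0.05. Undefined cases (all-zero differences,
constant inputs) are reported as absent rather than forced to a number.

## Experiment scales

The bundled experiments (test suite and `scripts/acceptance.py`) use 500
synthetic records (350/75/75 split), a BiLSTM width of 64, 10 epochs, and
100 MC passes — sizes chosen so a full run completes in minutes on a
single CPU while leaving the metadata benefit and all structural
properties clearly measurable. The full-scale defaults (BiLSTM 512, 100
epochs, N = 1000) remain the `ModelConfig`/CLI defaults.
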