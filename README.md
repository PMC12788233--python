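# leadrecon

Reconstruction of the standard 12-lead ECG from a single Lead I strip,
with clinical-metadata fusion and Monte Carlo-dropout uncertainty maps.

Wearable ECG devices record one or two leads, while most of clinical
electrocardiography is built on twelve. `leadrecon` addresses the gap for
monitoring and triage settings: given a 5.12-s Lead I window (512 samples
at 100 Hz) and five discretized metadata fields — QRS axis, T axis,
ventricular rate, QRS count, QRS duration — it predicts the remaining 11
leads (II, III, aVR, aVL, aVF, V1–V6) in mV, and quantifies, per lead and
time point, how much each reconstructed sample can be trusted.

The core model is a dual-branch network with late fusion

```
Lead I (1x512) ── Conv1d(32,k5)+ReLU x2 ── BiLSTM(512) ── dropout(0.2) ──┐
                                                                         ├─ concat ─ dropout(0.2) ─ FC(256)+ReLU ─ FC(11) → ŷ (11x512)
metadata one-hot (D=16) ── FC(32)+ReLU x3 ── broadcast over 512 steps ───┘
```

trained with Adam on MSE. Uncertainty comes from Monte Carlo dropout: the
two dropout sites stay active at inference and N stochastic passes give
the predictive standard deviation

σ(t) = sqrt( (1/N) Σᵢ (yᵢ(t) − ȳ(t))² ),  σ_norm(t) = σ(t) / maxₜ σ(t),

which is compared against the relative error
e(t) = |ŷ(t) − y(t)| / (|y(t)| + ε) through per-lead pooled correlations
and quartile tables. Baselines (early-fusion CNN–BiLSTM and a 1-D U-Net
with channel-repeated metadata), the full evaluation suite (per-lead and
P/QRS/ST/T-segment Pearson R, RMSE, 1-D SSIM; Wilcoxon / paired-t tests
with Holm correction) and a synthetic 12-lead generator make the whole
pipeline runnable and testable offline. See `docs/methods.md` for the
science and the design choices.

The neural layers are a self-contained numpy implementation with
analytic backprop (convolution, BiLSTM, dense, dropout, pooling, Adam),
gradient-checked against central differences in the test suite.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

trains the dual-branch model on 500 synthetic records with and without
metadata (10 epochs, BiLSTM width 64) and prints:

```
      time series only: R 0.742 +- 0.142 | RMSE 0.062 mV | SSIM 0.571 | segment R: P 0.59, QRS 0.67, ST 0.38, T 0.65, Ave 0.57
     time series + all: R 0.795 +- 0.122 | RMSE 0.054 mV | SSIM 0.512 | segment R: P 0.64, QRS 0.73, ST 0.40, T 0.72, Ave 0.62
R: wilcoxon, Holm-adjusted p = 6.83e-06 *
RMSE: paired-t, Holm-adjusted p = 3.74e-07 *
SSIM: wilcoxon, Holm-adjusted p = 3.96e-07 *
```

Reading this: with all five metadata features the held-out mean per-lead
correlation rises (0.742 → 0.795), the RMSE falls, and the QRS- and
T-segment correlations improve most — the synthetic chest leads depend on
the frontal axes, which Lead I alone cannot reveal but the axis categories
do. The paired tests (Holm-corrected, stars at p < 0.05) mark every
difference significant; note SSIM moves the other way at this short
training schedule, a reminder that the three metrics weight morphology
differently.
`examples/01_simulate_and_inspect.py` shows the generator's ground-truth
contracts and `examples/03_uncertainty_maps.py` renders a reliability
heatmap (`scratch/uncertainty_map.png`).

The same pipeline is scriptable from the shell:

```bash
leadrecon simulate --n 200 --seed 1 --out data/
leadrecon train --data data/ --condition all --seed 1 --out model
leadrecon evaluate --model model --data data/ --condition all --out report.csv
leadrecon uncertainty --model model --data data/ --condition all \
    --passes 100 --seed 1 --out unc/ --heatmap-leads II,V6
leadrecon run --seed 1 --out runs/full   # simulate..uncertainty, one manifest
```

## Layout

```
src/leadrecon/
  synth.py        # 12-lead dipole generator + population samplers
  preprocess.py   # decimation, windowing, discretization, one-hot, split
  nn.py           # numpy layers with analytic backprop + Adam
  model.py        # dual-branch / early-fusion / U-Net, training loop
  uncertainty.py  # MC dropout, sigma/sigma_norm/e, reliability analysis
  evaluate.py     # R / RMSE / 1-D SSIM, R peaks, segments, paired stats
  io.py           # CSV record I/O, metadata sidecar, run configs
  pipeline.py     # end-to-end orchestration with manifest
  cli.py          # thin click CLI
examples/         # narrative scripts, one per capability
docs/methods.md   # models, generator, numerical choices, limitations
scripts/acceptance.py
```
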