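# tinnigraph

Graph-based classification of two-class multichannel EEG — a tested,
reusable implementation of the similarity-graph + GCN-LSTM approach to
tinnitus detection, exercised end to end on synthetic EEG so that every
stage is verifiable without any external dataset.

**Who it is for:** researchers in clinical neurophysiology / EEG machine
learning who want the full pipeline — preprocessing, feature extraction,
ε-threshold graph construction, graph-neural classification, and honest
(transductive *and* inductive) cross-validated evaluation — as a library
and CLI rather than a one-off notebook.

## The method

1. **Preprocess.** Each recording is bandpass-filtered with a digital
   Butterworth filter (order n = 4, 1–40 Hz default; prototype magnitude
   |H(f)| = 1/√(1 + (f/ω_c)^(2n)), −3 dB at both band edges), applied
   zero-phase. Channels that are flat, dominated by high-frequency
   power, or uncorrelated with every neighbor are removed; epochs are
   cut at event markers and cleaned by PREP-style RANSAC (channels
   predicted from random channel subsets by least squares; epochs with
   too many inconsistent channels are flagged). Welch PSDs are computed
   per epoch and averaged over channels.
2. **Features.** Each retained epoch becomes a fixed-order vector:
   time-domain statistics (mean, σ, RMS, σ²), PSD descriptors
   (argmax_f PSD, Σf·PSD/ΣPSD, ∫PSD df), a K = 8 Piecewise Aggregate
   Approximation, spectrogram time-frequency descriptors, and the mean
   absolute successive difference. Columns are min–max rescaled to [0, 1].
3. **Graph.** One node per epoch; an undirected edge joins nodes i, j
   iff ‖X_i − X_j‖₂ < ε (strict; ε = 0.2 default). The GCN operates on
   the symmetric-normalized adjacency with self-loops,
   Â = A + I, D̂_ii = Σ_j Â_ij, propagating with D̂^(−1/2) Â D̂^(−1/2).
4. **Model.** L = 3 graph-convolution layers
   X_l = ReLU(D̂^(−1/2) Â D̂^(−1/2) X_{l−1} W_l), the final embedding
   reshaped into T = 4 pseudo-time steps, a single LSTM, and a fully
   connected layer on the last hidden state: Output = FC(H_T).
   Training is cross-entropy + Adam + weight decay + dropout with early
   stopping, implemented on a small gradient-checked numpy autodiff
   engine (no GPU, fully deterministic given a seed).
5. **Evaluate.** Stratified 10-fold cross-validation (grouped by
   recording), pooled confusion counts and row-normalized rates,
   accuracy, precision, recall ≡ sensitivity, F1, Cohen's κ, AUC, and a
   PCA projection of the penultimate activations. Transductive mode
   reproduces the whole-dataset-graph protocol (and logs its leakage
   risk); inductive mode rebuilds per-fold graphs from training rows
   only.

The synthetic generator produces balanced two-class cohorts of
spatially correlated 1/f EEG with configurable per-band oscillation
amplitudes (default: a 2:1 gamma-band amplitude contrast in the
"tinnitus-like" class), event markers, and injectable artifacts
(eye blinks, mains hum, flat/noisy channels) with a ground-truth log.
See `docs/methods.md` for every model detail and limitation.

## Worked example

```python
from tinnigraph import PipelineConfig, run_all

report = run_all(PipelineConfig(seed=1))
cv = report["cv"]["pooled"]
print("nodes:", report["stages"]["graph"]["n_nodes"])
print("accuracy:", round(cv["accuracy"], 4))
print("f1:", round(cv["f1"], 4), " kappa:", round(cv["kappa"], 4),
      " auc:", round(cv["auc"], 4))
print("confusion rates:", {k: round(v, 3) for k, v in cv["rates"].items()})
```

prints

```
nodes: 1200
accuracy: 0.9667
f1: 0.967  kappa: 0.9333  auc: 0.9971
confusion rates: {'tp': 0.977, 'fn': 0.023, 'tn': 0.957, 'fp': 0.043}
```

Forty synthetic recordings (20 per class, 60 s, 16 channels, 256 Hz)
yield 1200 one-second epochs; the configured 2:1 gamma amplitude
contrast is recovered at 96.7% pooled 10-fold accuracy, with the
row-normalized confusion rates showing the per-class error split. Runtime
is a few minutes on one CPU. Rerunning the identical pipeline on a
zero-effect dataset (equal band powers) in inductive mode yields pooled
accuracy ≈ 0.48 — chance level, confirming that the evaluation protocol
does not leak labels.

The same pipeline is scriptable from the shell:

```bash
tinnigraph run-all report.json --seed 1
tinnigraph simulate data/ --n-per-class 5 --duration 20
tinnigraph preprocess data/ epochs/
tinnigraph features epochs/ features.csv
tinnigraph graph features.csv graph.graphml --epsilon 0.2
tinnigraph evaluate graph.graphml cv.json --n-folds 5 --mode inductive
```

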