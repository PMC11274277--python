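# Methods

`tinnigraph` implements a graph-based classifier for two-class
multichannel EEG (control vs tinnitus-like activity): cleaned epochs are
summarized as feature vectors, the vectors become nodes of an
ε-threshold similarity graph, and a GCN-LSTM assigns each node a class.
This note records the models, the defaults and why they were chosen, and
what the synthetic validation does and does not demonstrate.

## Synthetic data model

Real tinnitus EEG corpora are not required anywhere; the `synth` module
generates the study conditions. Per channel c of a recording,

    x_c(t) = s · (g_c · b(t) + ρ · n_c(t)) + Σ_bands a_k · h_c · sin(2π f_k t + φ_k)

where `b` is a shared 1/f^α Gaussian background source (α = 1 by
default, the canonical EEG spectral slope), `n_c` is independent 1/f^α
noise, `g_c ~ U(0.5, 1.5)` and `h_c ~ U(0.8, 1.2)` are channel gains,
`s` the noise scale (1 a.u.) and `ρ = 0.3` the relative amplitude of
channel-independent noise. The shared source makes channels strongly
correlated (pairwise r ≈ 0.9+), which is what scalp montages look like
and what both the low-correlation bad-channel criterion and the
channel-prediction RANSAC rely on. Each band contributes a single
sinusoid with frequency drawn uniformly in the band and one phase shared
across channels.

Defaults: 16 channels, 256 Hz, 60 s per recording, 20 recordings per
class, event markers every 2 s. The class contrast is band-limited
oscillation amplitude: both classes carry alpha (8–12 Hz, amplitude 1.0),
and the "tinnitus" class carries gamma (30–40 Hz) at amplitude 1.0
versus 0.5 in controls — a 2:1 amplitude (4:1 power) contrast, in line
with the auditory-hyperactivity picture of tinnitus. All of this is
configuration, not assumption: `band_powers` accepts any per-class band
map, and setting both classes equal produces the null dataset used for
the leakage check.

Injectable artifacts (with an exact ground-truth log) are: eye-blink
transients — Gaussian bumps of 0.4 s whose peak is `multiplier ×`
channel standard deviation, applied to a frontal subset of channels with
±0.15 s per-channel latency jitter (a blink is not a single scaled
template across electrodes, and a perfectly common-mode transient would
be invisible to any cross-channel consistency check); 50 Hz mains hum;
exactly-constant flat channels; and broadband-noise channels.

What the generator does *not* emulate: volume conduction with realistic
lead fields, non-stationarity, inter-subject montage variation, real
tinnitus electrophysiology, or therapy effects. Passing the end-to-end
checks therefore shows that the pipeline recovers a band-power class
contrast it was configured to contain — not that it detects tinnitus in
real patients.

## Preprocessing

* **Bandpass.** Digital Butterworth of order 4, passband 1–40 Hz by
  default (the conventional EEG range; the cutoff "ranges" 0.5–1 Hz and
  40–50 Hz are exposed as configuration, we take the inner edges).
  Application is zero-phase (forward–backward), which preserves marker
  timing for epoching at the price of doubling the effective order; the
  *designed* single-pass magnitude is what the filter-analytics checks
  assert (−3 dB at both band edges for any order — the Butterworth
  property).
* **Bad channels.** Three criteria, union-flagged, thresholds
  configurable: variance < 1e−10 (flat), power fraction above 40 Hz
  > 0.5 (high-frequency noise), best absolute Pearson correlation with
  any other channel < 0.4 (disconnected/isolated channel). With fewer
  than 3 channels the correlation criterion is skipped with a warning.
* **Epochs.** One epoch per marker, default window [0, 1] s; windows that
  do not fit inside the recording are dropped and logged, never
  truncated.
* **RANSAC cleaning** (PREP lineage, scored per epoch). For each epoch,
  20 random channel subsets of 25% of the channels are drawn once per
  run; each channel is predicted by least squares from every subset that
  excludes it, the per-sample median of those predictions is the
  consensus, and a channel whose observed signal correlates with its
  consensus below 0.85 is an outlier in that epoch. Epochs with more
  than 15% outlier channels are flagged `rejected` — flagged, never
  deleted, so the cleaning step is auditable downstream. The
  correlation threshold is higher than the 0.75 habitually used on real
  scalp data because the synthetic montage is more strongly correlated
  than a real one; both numbers are parameters. Seeded and
  deterministic.
* **PSD.** Welch (Hann window, segment = min(epoch, 1 s), 50% overlap)
  per epoch per channel, in power/Hz; the bare periodogram |X(f)|² is
  available as `method="periodogram"` for literal fidelity to the
  squared-magnitude definition. Channel-averaged PSD is the arithmetic
  mean over channels.

## Features

Per retained epoch, computed on the channel-averaged signal (z-scored
per epoch) and the channel-averaged PSD of the unnormalized data, in a
fixed documented column order (20 columns with the default K = 8):

mean, std, rms, variance | max_freq, mean_freq (power-weighted),
bandwidth (trapezoidal PSD integral) | paa_1..paa_8 | spec_max_time,
spec_mean_time_freq, spec_max_freq_per_time, spec_mean_freq_over_time |
avg_amplitude_change.

Notes on deliberate choices:

* Per-epoch z-scoring makes the mean/std columns nearly constant; they
  are kept for schema fidelity, and the min–max rescaling maps constant
  columns to 0. The class signal lives mainly in the spectral columns
  (mean_freq, bandwidth), which are computed before normalization and
  so retain absolute band power.
* PAA uses the standard fractional-boundary definition (exact via
  k-fold upsampling); when K divides the length, segment means preserve
  the signal mean exactly.
* The spectrogram uses Hann windows of 0.25 s with 50% overlap.
* A per-channel mode (`per_channel=True`) concatenates the same features
  channel by channel for users who prefer not to average first.
* Columns are min–max rescaled to [0, 1] over the pooled dataset by
  default: a Euclidean edge threshold of 0.2 is meaningless without a
  fixed feature scale. Raw mode is available.

## Similarity graph

One node per sample row; edge iff Euclidean distance < ε, strictly
(ties at exactly ε are excluded), with ε = 0.2 by default. The
construction is exhaustive O(n²) and is verified against a literal
double-loop oracle on random instances.

An honest caveat, measured rather than hidden: with the default
20-dimensional unit-interval feature space, pairwise distances
concentrate far above 0.2, so the default graph is extremely sparse —
typically edgeless — and the normalized adjacency reduces to the
identity, making the GCN act per-node (self-loops only). ε is a free
parameter precisely because the meaningful threshold depends on the
feature space; the graph machinery is exercised at larger ε throughout
the test suite. The symmetric normalization D̂^(−1/2)(A+I)D̂^(−1/2)
always has spectrum in [−1, 1] and gives isolated nodes degree 1, so no
division by zero arises.

## GCN-LSTM

Three GCN layers (widths 64-64-32, no bias, ReLU), dropout 0.3 between
layers during training; the final 32-wide embedding is chunked into
T = 4 contiguous pseudo-time steps of width 8; a single LSTM layer
(hidden 32, standard input/forget/cell/output gates, zero initial
states) consumes the steps; a fully connected layer maps the last hidden
state to 2 logits. The pseudo-time reshape is the one genuinely ill-posed
piece of the architecture — a static node embedding has no time axis —
and it is implemented as the literal invertible chunking rather than
disguised as anything deeper.

Training: softmax cross-entropy on training-mask nodes, Adam
(lr 1e−3), L2 weight decay 5e−4, early stopping on validation loss with
patience 50 and best-weight restoration, budget 1500 epochs for a single
model. Gradients come from a small reverse-mode autodiff engine written
for this package and gradient-checked against central finite differences
for every op and for composite networks. Glorot-uniform initialization,
all randomness seeded; training is bit-reproducible.

The cross-validation driver defaults to a smaller per-fold budget
(300 epochs, patience 30): with early stopping the larger budget only
adds wall time on the synthetic task (best epochs land between ~60 and
~290), and the driver trains 10 models per mode.

## Evaluation protocol

Ten-fold cross-validation; the validation set of fold k is the test set
of fold k+1. Two modes:

* **Transductive** (default, protocol-faithful): one global graph; test
  nodes are present — as nodes, edges, and feature-scaling participants —
  while training. This is a leakage channel and is logged as such.
* **Inductive:** per fold, the graph is rebuilt from train+validation
  rows only; the trained weights never see a test row. At evaluation
  the test rows attach through their own distances.

Folds are stratified at the *recording* level whenever provenance is
available (StratifiedGroupKFold): epochs of one recording share its
idiosyncratic oscillation frequency and channel gains, so epoch-level
folds would let a model identify a held-out epoch's recording from its
siblings in training and read off the label — the zero-effect inductive
null would then sit far above chance for reasons that have nothing to do
with class signal. With group folds the null sits at ~0.48–0.5 and the
2:1 gamma contrast is recovered at pooled accuracy ≈ 0.97 across seeds.
Epoch-level stratification remains available by passing `groups=None`
explicitly.

Metrics are computed from confusion counts by their definitions
(accuracy, precision, recall ≡ sensitivity — one value echoed under both
keys —, F1, Cohen's κ), with zero-denominator cases reported as null
plus a reason; AUC is the rank statistic over pooled class-1
probabilities. Confusion is reported both as raw counts and row-normalized
rates (each true-class row sums to 1). PCA of the penultimate (last LSTM
hidden state) activations provides the 2-D separability scatter, with a
deterministic sign convention (largest-magnitude loading positive).

## Determinism and numerics

A single master seed drives recording seeds (spawned via
`SeedSequence`), RANSAC subsets, fold shuffles, weight initialization,
and dropout; per-fold model seeds are derived as `seed + 1000·(fold+1)`.
Reports are serialized with sorted keys and no timestamps, so a repeated
run is byte-identical. Degenerate inputs are handled explicitly: all-zero
PSDs and spectrograms yield zero-valued features with a warning; flat
signals cannot be z-scored and raise; constant feature columns rescale
to 0; isolated graph nodes keep degree 1.

## Problem sizes

The shipped validation runs at desk scale by design: 2 × 20 recordings
of 60 s (1200 epochs/nodes) for the end-to-end checks, 100 random
instances for each oracle-equivalence check, 1000 random vectors for the
metric identities. These sizes are large enough for the stochastic
checks to be stable across seeds while keeping a full validation run in
minutes on one CPU.

## Known limitations

* The ε = 0.2 default yields a near-empty graph in the default feature
  space (see above); users wanting graph smoothing should set ε to a
  quantile of observed pairwise distances.
* The LSTM-over-pseudo-time construction cannot model real temporal
  structure across epochs; it is faithful to the architecture it
  implements, not a recommendation.
* Transductive accuracy mixes class signal with train/test coupling;
  inductive numbers are the ones to quote for generalization.
* The synthetic generator's realism limits are listed above; no claim
  about real-EEG performance is made or tested.
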