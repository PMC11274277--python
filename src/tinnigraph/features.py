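"""Per-epoch feature extraction.

Each retained epoch is summarized by a fixed-order vector of
time-domain statistics, frequency-domain descriptors of the
channel-averaged power spectral density, a Piecewise Aggregate
Approximation (PAA) of the signal, spectrogram-based time-frequency
descriptors, and the mean absolute successive amplitude change.

By default the time-domain signal is the channel average, normalized to
zero mean and unit variance before feature computation; spectral
features are computed on the channel-averaged PSD of the unnormalized
epoch, so absolute band power remains informative. A per-channel mode
concatenates the same features channel by channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet, SpectralDensity

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "normalize_signal",
    "time_domain_features",
    "frequency_domain_features",
    "paa_transform",
    "time_frequency_features",
    "amplitude_change_features",
    "build_feature_matrix",
    "concat_feature_matrices",
    "rescale_unit_interval",
    "feature_names",
]

logger = logging.getLogger(__name__)


def normalize_signal(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rescaling (population standard deviation)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std()
    if sd == 0:
        raise ValueError("flat signal: variance is zero, cannot normalize")
    return (x - x.mean()) / sd


def time_domain_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, std, rms, variance) with population conventions."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std()
    return float(x.mean()), float(sd), float(np.sqrt(np.mean(x ** 2))), float(sd ** 2)


def frequency_domain_features(freqs: np.ndarray,
                              psd: np.ndarray) -> tuple[float, float, float]:
    """(max_freq, mean_freq, bandwidth) of one PSD row.

    max_freq is the frequency of peak power; mean_freq is the
    power-weighted mean frequency; bandwidth is the trapezoidal integral
    of the PSD over frequency (total power).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size < 2:
        raise ValueError("need at least 2 frequency bins")
    total = psd.sum()
    if total <= 0:
        logger.warning("all-zero PSD: frequency features default to 0")
        return 0.0, 0.0, 0.0
    max_freq = float(freqs[int(np.argmax(psd))])
    mean_freq = float((freqs * psd).sum() / total)
    bandwidth = float(np.trapezoid(psd, freqs))
    return max_freq, mean_freq, bandwidth


def paa_transform(x: np.ndarray, n_segments: int) -> np.ndarray:
    """Piecewise Aggregate Approximation with fractional boundary weighting.

    Segment s is the mean of the samples covering the s-th of n_segments
    equal-length pieces of the index axis; when the length is not
    divisible by n_segments, boundary samples contribute fractionally.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 1 <= n_segments <= n:
        raise ValueError(f"need 1 <= n_segments <= len(x), got {n_segments} vs {n}")
    if n % n_segments == 0:
        return x.reshape(n_segments, -1).mean(axis=1)
    # Exact fractional PAA: k-fold upsampling makes the split even.
    return np.repeat(x, n_segments).reshape(n_segments, n).mean(axis=1)


def time_frequency_features(x: np.ndarray, fs: float,
                            segment_seconds: float = 0.25,
                            overlap: float = 0.5) -> tuple[float, float, float, float]:
    """Spectrogram-derived descriptors of one epoch.

    Returns (spec_max_time, spec_mean_time_freq, spec_max_freq_per_time,
    spec_mean_freq_over_time):

    * spec_max_time — time (s) of the frame with maximum total energy;
    * spec_mean_time_freq — energy-weighted mean of the frame times;
    * spec_max_freq_per_time — mean over frames of the per-frame peak frequency;
    * spec_mean_freq_over_time — mean over frames of the per-frame
      power-weighted mean frequency.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, int(round(segment_seconds * fs)))
    if x.size < nperseg:
        raise ValueError("signal shorter than spectrogram segment")
    noverlap = int(round(overlap * nperseg))
    f, t, S = sps.spectrogram(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=noverlap)
    if t.size == 1:
        logger.warning("single-frame spectrogram: time-frequency features degenerate")
    energy = S.sum(axis=0)
    total = energy.sum()
    if total <= 0:
        logger.warning("all-zero signal: time-frequency features default to 0")
        return 0.0, 0.0, 0.0, 0.0
    spec_max_time = float(t[int(np.argmax(energy))])
    spec_mean_time_freq = float((t * energy).sum() / total)
    peak_freqs = f[np.argmax(S, axis=0)]
    spec_max_freq_per_time = float(peak_freqs.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        mf = np.where(energy > 0, (f[:, None] * S).sum(axis=0) / energy, 0.0)
    spec_mean_freq_over_time = float(mf.mean())
    return (spec_max_time, spec_mean_time_freq,
            spec_max_freq_per_time, spec_mean_freq_over_time)


def amplitude_change_features(x: np.ndarray) -> float:
    """Mean absolute successive difference |x[i+1] - x[i]|."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.diff(x)).mean())


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    n_paa_segments: int = 8
    normalize: bool = True            # z-score the epoch signal before features
    rescale: bool = True              # min-max rescale columns to [0, 1]
    per_channel: bool = False         # concatenate features per channel
    spectrogram_segment_seconds: float = 0.25
    spectrogram_overlap: float = 0.5


def feature_names(config: FeatureConfig) -> list[str]:
    base = ["mean", "std", "rms", "variance",
            "max_freq", "mean_freq", "bandwidth"]
    base += [f"paa_{i + 1}" for i in range(config.n_paa_segments)]
    base += ["spec_max_time", "spec_mean_time_freq",
             "spec_max_freq_per_time", "spec_mean_freq_over_time",
             "avg_amplitude_change"]
    return base


@dataclass
class FeatureMatrix:
    """Samples x named features plus binary labels and provenance."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("rows of X must match length of y")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("columns of X must match feature_names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        for col in self.provenance.columns:
            df[col] = self.provenance[col].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        prov_cols = [c for c in ("subject", "epoch") if c in df.columns]
        names = [c for c in df.columns if c not in prov_cols + ["label"]]
        return cls(X=df[names].to_numpy(float), y=df["label"].to_numpy(int),
                   feature_names=names, provenance=df[prov_cols].copy())


def _epoch_features(xbar: np.ndarray, freqs: np.ndarray, psd_bar: np.ndarray,
                    fs: float, config: FeatureConfig) -> np.ndarray:
    if config.normalize and xbar.std() > 0:
        xsig = normalize_signal(xbar)
    else:
        xsig = xbar
    row = list(time_domain_features(xsig))
    row += list(frequency_domain_features(freqs, psd_bar))
    row += list(paa_transform(xsig, config.n_paa_segments))
    row += list(time_frequency_features(
        xsig, fs, config.spectrogram_segment_seconds, config.spectrogram_overlap))
    row.append(amplitude_change_features(xsig))
    return np.array(row)


def build_feature_matrix(epochs: EpochSet, sd: SpectralDensity,
                         config: FeatureConfig | None = None,
                         subject: str | None = None) -> FeatureMatrix:
    """One feature row per retained (non-rejected) epoch.

    Rows with any non-finite feature are excluded with a log message.
    Column rescaling to [0, 1] is deferred to :func:`rescale_unit_interval`
    so that matrices from several recordings can be pooled first.
    """
    cfg = config or FeatureConfig()
    if sd.n_epochs != epochs.n_epochs:
        raise ValueError("SpectralDensity and EpochSet epoch counts differ")
    keep = epochs.retained()
    if keep.size < 1:
        raise ValueError("no retained epochs")
    subject = subject if subject is not None else (epochs.subject or "")

    names = feature_names(cfg)
    if cfg.per_channel:
        names = [f"{n}_ch{c}" for c in range(epochs.n_channels) for n in names]

    rows, labels, prov = [], [], []
    for e in keep:
        if cfg.per_channel:
            parts = [
                _epoch_features(epochs.data[e, c], sd.freqs, sd.power[e, c],
                                epochs.fs, cfg)
                for c in range(epochs.n_channels)
            ]
            row = np.concatenate(parts)
        else:
            xbar = epochs.data[e].mean(axis=0)
            psd_bar = sd.power[e].mean(axis=0)
            row = _epoch_features(xbar, sd.freqs, psd_bar, epochs.fs, cfg)
        if not np.all(np.isfinite(row)):
            logger.warning("epoch %d produced non-finite features; excluded", e)
            continue
        rows.append(row)
        labels.append(0 if epochs.labels is None else int(epochs.labels[e]))
        prov.append({"subject": subject, "epoch": int(e)})

    if not rows:
        raise ValueError("all epochs produced non-finite features")
    return FeatureMatrix(X=np.stack(rows), y=np.array(labels),
                         feature_names=names,
                         provenance=pd.DataFrame(prov))


def concat_feature_matrices(parts: list[FeatureMatrix]) -> FeatureMatrix:
    if not parts:
        raise ValueError("nothing to concatenate")
    names = parts[0].feature_names
    for p in parts[1:]:
        if p.feature_names != names:
            raise ValueError("feature schemas differ")
    return FeatureMatrix(
        X=np.concatenate([p.X for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        feature_names=list(names),
        provenance=pd.concat([p.provenance for p in parts], ignore_index=True))


def rescale_unit_interval(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise min-max rescaling to [0, 1]; constant columns map to 0.

    A fixed-scale feature space is what makes the Euclidean edge threshold
    of the similarity graph meaningful.
    """
    lo = fm.X.min(axis=0)
    rng = fm.X.max(axis=0) - lo
    safe = np.where(rng > 1e-12, rng, 1.0)
    X = np.where(rng > 1e-12, (fm.X - lo) / safe, 0.0)
    return FeatureMatrix(X=X, y=fm.y.copy(), feature_names=list(fm.feature_names),
                         provenance=fm.provenance.copy())
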