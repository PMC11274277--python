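"""EEG preprocessing: bandpass filtering, bad-channel detection, event
definition, epoching, RANSAC epoch cleaning, and Welch power spectral
density estimation.

The bandpass is a digital Butterworth designed with scipy and applied
zero-phase (forward-backward), which preserves event timing for epoching
at the cost of doubling the effective order. Epoch cleaning follows the
PREP-pipeline reading of RANSAC: each channel is predicted from random
channel subsets by least squares within each epoch; channels whose
observed signal decorrelates from the consensus prediction are outliers,
and epochs with too many outlier channels are flagged (never deleted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .containers import EpochSet, RawRecording, SpectralDensity

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "butterworth_prototype_gain",
    "apply_filter",
    "BadChannelThresholds",
    "BadChannelReport",
    "detect_bad_channels",
    "remove_bad_channels",
    "define_events",
    "make_epochs",
    "RansacParams",
    "ransac_clean",
    "compute_psd",
    "average_psd",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """A designed digital Butterworth bandpass (second-order sections)."""

    order: int
    low_cut: float
    high_cut: float
    fs: float
    sos: np.ndarray

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response H(f) of the designed digital filter on a Hz grid."""
        _, h = sps.sosfreqz(self.sos, worN=np.asarray(freqs, dtype=float), fs=self.fs)
        return h

    def magnitude(self, freqs: np.ndarray) -> np.ndarray:
        return np.abs(self.frequency_response(freqs))


def butterworth_prototype_gain(f: np.ndarray | float, cutoff: float, order: int) -> np.ndarray | float:
    """Closed-form lowpass Butterworth magnitude 1 / sqrt(1 + (f/fc)^(2n)).

    This is the analytic prototype response; at f = cutoff it equals
    1/sqrt(2) for every order.
    """
    f = np.asarray(f, dtype=float)
    out = 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))
    return out if out.ndim else float(out)


def design_bandpass(order: int = 4, low_cut: float = 1.0, high_cut: float = 40.0,
                    fs: float = 256.0) -> FilterSpec:
    """Design a digital Butterworth bandpass; band edges sit at the -3 dB points."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0 < low_cut < high_cut:
        raise ValueError("need 0 < low_cut < high_cut")
    if high_cut >= fs / 2:
        raise ValueError(f"high_cut {high_cut} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [low_cut, high_cut], btype="bandpass", fs=fs, output="sos")
    return FilterSpec(order=order, low_cut=low_cut, high_cut=high_cut, fs=fs, sos=sos)


def apply_filter(rec: RawRecording, spec: FilterSpec) -> RawRecording:
    """Zero-phase (forward-backward) filtering of every channel."""
    if abs(rec.fs - spec.fs) > 1e-9:
        raise ValueError(f"recording fs {rec.fs} != filter fs {spec.fs}")
    out = rec.copy()
    out.data = sps.sosfiltfilt(spec.sos, rec.data, axis=1)
    out.filtered = True
    return out


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BadChannelThresholds:
    """Flatness = variance floor; HF noise = fraction of power above ``hf_cut``;
    low correlation = best absolute Pearson correlation with any other channel."""

    flat_variance: float = 1e-10
    hf_cut: float = 40.0
    hf_power_fraction: float = 0.5
    min_correlation: float = 0.4


@dataclass
class BadChannelReport:
    channel_labels: list[str]
    flat: np.ndarray
    hf_noise: np.ndarray
    low_correlation: np.ndarray
    variance: np.ndarray
    hf_fraction: np.ndarray
    best_correlation: np.ndarray
    thresholds: BadChannelThresholds

    @property
    def bad(self) -> np.ndarray:
        return self.flat | self.hf_noise | self.low_correlation

    @property
    def bad_channels(self) -> list[int]:
        return list(np.flatnonzero(self.bad))

    def reasons(self, ch: int) -> list[str]:
        out = []
        if self.flat[ch]:
            out.append("flat")
        if self.hf_noise[ch]:
            out.append("hf_noise")
        if self.low_correlation[ch]:
            out.append("low_correlation")
        return out


def detect_bad_channels(rec: RawRecording,
                        thresholds: BadChannelThresholds | None = None) -> BadChannelReport:
    """Flag channels that are flat, dominated by high-frequency power, or
    uncorrelated with every other channel."""
    thr = thresholds or BadChannelThresholds()
    C = rec.n_channels
    var = rec.data.var(axis=1)
    flat = var < thr.flat_variance

    nperseg = min(rec.n_samples, int(rec.fs))
    freqs, psd = sps.welch(rec.data, fs=rec.fs, nperseg=nperseg, axis=1)
    total = psd.sum(axis=1)
    hi = psd[:, freqs > thr.hf_cut].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hf_frac = np.where(total > 0, hi / total, 0.0)
    hf = hf_frac > thr.hf_power_fraction

    best = np.zeros(C)
    if C >= 3:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(rec.data)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        best = np.abs(corr).max(axis=1)
        low_corr = best < thr.min_correlation
    else:
        logger.warning("fewer than 3 channels: correlation criterion skipped")
        low_corr = np.zeros(C, dtype=bool)

    return BadChannelReport(
        channel_labels=list(rec.channel_labels), flat=flat, hf_noise=hf,
        low_correlation=low_corr, variance=var, hf_fraction=hf_frac,
        best_correlation=best, thresholds=thr)


def remove_bad_channels(rec: RawRecording,
                        report: BadChannelReport) -> tuple[RawRecording, BadChannelReport]:
    """Return a reduced recording with flagged channels dropped."""
    keep = np.flatnonzero(~report.bad)
    if keep.size == 0:
        raise ValueError("all channels flagged bad")
    out = replace(
        rec.copy(), data=rec.data[keep],
        channel_labels=[rec.channel_labels[i] for i in keep])
    return out, report


# ---------------------------------------------------------------------------
# Events and epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    sample: int
    time: float
    marker_id: int


def define_events(rec: RawRecording) -> list[Event]:
    """One event per marker, sorted by sample index."""
    events = [Event(sample=s, time=s / rec.fs, marker_id=m)
              for s, m in sorted(rec.markers)]
    return events


def make_epochs(rec: RawRecording, events: list[Event],
                tmin: float = 0.0, tmax: float = 1.0) -> EpochSet:
    """Cut one epoch per event; windows falling outside the recording are
    dropped (and logged), not truncated."""
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    n_t = int(round((tmax - tmin) * rec.fs))
    if n_t > rec.n_samples:
        raise ValueError("epoch window longer than recording")
    starts = []
    for ev in events:
        s0 = ev.sample + int(round(tmin * rec.fs))
        if s0 < 0 or s0 + n_t > rec.n_samples:
            logger.info("event at sample %d dropped: window outside recording", ev.sample)
            continue
        starts.append(s0)
    data = np.stack([rec.data[:, s:s + n_t] for s in starts]) if starts else \
        np.empty((0, rec.n_channels, n_t))
    labels = None
    if rec.label is not None:
        labels = np.full(len(starts), rec.label, dtype=int)
    return EpochSet(data=data, fs=rec.fs, tmin=tmin, tmax=tmax, labels=labels,
                    subject=rec.subject)


# ---------------------------------------------------------------------------
# RANSAC epoch cleaning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RansacParams:
    n_resamples: int = 20
    sample_fraction: float = 0.25        # fraction of channels per predictor subset
    correlation_threshold: float = 0.85  # outlier if corr(prediction, observed) below
    bad_fraction_threshold: float = 0.15  # reject epoch if outlier-channel fraction above
    seed: int = 0


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if sa == sb == 0 else 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def ransac_clean(epochs: EpochSet, params: RansacParams | None = None) -> EpochSet:
    """PREP-style RANSAC epoch cleaning.

    For each epoch, every channel is predicted by least squares from each of
    ``n_resamples`` random channel subsets that exclude it; the median
    prediction is compared with the observation, and a Pearson correlation
    below ``correlation_threshold`` marks the channel as an outlier within
    that epoch. Epochs whose outlier-channel fraction exceeds
    ``bad_fraction_threshold`` are flagged as rejected.
    """
    p = params or RansacParams()
    E, C, S = epochs.n_epochs, epochs.n_channels, epochs.n_times
    if C < 4:
        raise ValueError("RANSAC needs at least 4 channels")
    if E < 5:
        raise ValueError("RANSAC needs at least 5 epochs")
    rng = np.random.default_rng(p.seed)
    k = max(2, int(round(p.sample_fraction * C)))
    subsets = [np.sort(rng.choice(C, size=k, replace=False))
               for _ in range(p.n_resamples)]
    all_ch = np.arange(C)

    rejected = np.zeros(E, dtype=bool)
    reasons = [""] * E
    outlier_fraction = np.zeros(E)
    for e in range(E):
        X = epochs.data[e]                         # C x S
        preds: list[list[np.ndarray]] = [[] for _ in range(C)]
        for sub in subsets:
            targets = np.setdiff1d(all_ch, sub, assume_unique=False)
            P = X[sub].T                           # S x k
            G = P.T @ P + 1e-12 * np.eye(k)
            B = np.linalg.solve(G, P.T @ X[targets].T)
            Yhat = P @ B                           # S x len(targets)
            for j, c in enumerate(targets):
                preds[c].append(Yhat[:, j])
        n_out = 0
        for c in range(C):
            if preds[c]:
                pred = np.median(np.stack(preds[c]), axis=0)
            else:  # channel appeared in every subset: predict from all others
                P = np.delete(X, c, axis=0).T
                G = P.T @ P + 1e-12 * np.eye(P.shape[1])
                pred = P @ np.linalg.solve(G, P.T @ X[c])
            if _safe_corr(pred, X[c]) < p.correlation_threshold:
                n_out += 1
        outlier_fraction[e] = n_out / C
        if outlier_fraction[e] > p.bad_fraction_threshold:
            rejected[e] = True
            reasons[e] = f"ransac: {n_out}/{C} outlier channels"

    out = EpochSet(data=epochs.data.copy(), fs=epochs.fs, tmin=epochs.tmin,
                   tmax=epochs.tmax,
                   labels=None if epochs.labels is None else epochs.labels.copy(),
                   rejected=rejected, reject_reasons=reasons,
                   subject=epochs.subject)
    return out


# ---------------------------------------------------------------------------
# Spectral density
# ---------------------------------------------------------------------------

def compute_psd(epochs: EpochSet, segment_seconds: float = 1.0,
                overlap: float = 0.5, window: str = "hann",
                method: str = "welch") -> SpectralDensity:
    """Per-epoch, per-channel PSD in power/Hz.

    ``method="welch"`` averages windowed periodograms (default);
    ``method="periodogram"`` is the bare squared-magnitude spectrum.
    """
    S = epochs.n_times
    if method == "periodogram":
        freqs, power = sps.periodogram(epochs.data, fs=epochs.fs, axis=-1)
        return SpectralDensity(freqs=freqs, power=power)
    if method != "welch":
        raise ValueError(f"unknown PSD method {method!r}")
    nperseg = min(S, int(round(segment_seconds * epochs.fs)))
    if nperseg > S:
        raise ValueError("PSD segment longer than epoch")
    noverlap = int(round(overlap * nperseg))
    freqs, power = sps.welch(epochs.data, fs=epochs.fs, window=window,
                             nperseg=nperseg, noverlap=noverlap, axis=-1)
    return SpectralDensity(freqs=freqs, power=power)


def average_psd(sd: SpectralDensity) -> SpectralDensity:
    """Arithmetic mean over the channel axis; output keeps a channel axis of 1."""
    if sd.n_channels < 1:
        raise ValueError("need at least one channel")
    return SpectralDensity(freqs=sd.freqs, power=sd.power.mean(axis=1, keepdims=True))
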