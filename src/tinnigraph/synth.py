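"""Synthetic two-class multichannel EEG generator.

Generates labeled recordings whose structure matches what the downstream
pipeline assumes: 1/f-colored background activity shared across channels
(scalp EEG is strongly spatially correlated), band-limited oscillations
whose amplitude may differ between the two classes, periodic event
markers, and injectable artifacts (eye blinks, mains hum, flat channels,
broadband-noise channels) with a ground-truth log.

The class contrast defaults to elevated gamma-band amplitude in class 1
(the "tinnitus-like" class), consistent with the auditory-cortex
hyperactivity literature; every amplitude is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .containers import RawRecording

__all__ = [
    "BandSpec",
    "SynthConfig",
    "ArtifactSpec",
    "ArtifactEvent",
    "generate_recording",
    "inject_artifacts",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class BandSpec:
    """One band-limited oscillatory component: [low, high] Hz at a given amplitude (a.u.)."""

    low: float
    high: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def default_band_powers() -> dict[int, dict[str, BandSpec]]:
    """Default class contrast: equal alpha, 2:1 gamma amplitude (class 1 : class 0)."""
    return {
        0: {"alpha": BandSpec(8.0, 12.0, 1.0), "gamma": BandSpec(30.0, 40.0, 0.5)},
        1: {"alpha": BandSpec(8.0, 12.0, 1.0), "gamma": BandSpec(30.0, 40.0, 1.0)},
    }


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the synthetic cohort.

    ``spatial_noise`` is the per-channel independent noise amplitude relative
    to the shared background source; small values make channels strongly
    correlated, as on a real scalp montage.
    """

    n_subjects_per_class: int = 20
    n_channels: int = 16
    fs: float = 256.0
    duration: float = 60.0
    band_powers: Mapping[int, Mapping[str, BandSpec]] = field(
        default_factory=default_band_powers)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    spatial_noise: float = 0.3
    marker_period: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        if self.marker_period <= 0:
            raise ValueError("marker_period must be positive")
        if self.noise_scale < 0 or self.spatial_noise < 0:
            raise ValueError("noise amplitudes must be >= 0")
        nyq = self.fs / 2.0
        for cls, bands in self.band_powers.items():
            for name, b in bands.items():
                if b.high >= nyq:
                    raise ValueError(
                        f"band '{name}' of class {cls} has edge {b.high} Hz "
                        f">= Nyquist ({nyq} Hz)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _colored_noise(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(config: SynthConfig, class_label: int,
                       seed: int | np.random.SeedSequence | None = None,
                       subject: str | None = None) -> RawRecording:
    """Generate one labeled recording.

    Signal model per channel c:
        x_c(t) = noise_scale * (g_c * b(t) + spatial_noise * n_c(t))
                 + sum_bands amplitude * h_c * sin(2 pi f t + phi)
    with b a shared 1/f^alpha source, n_c independent 1/f^alpha noise,
    g_c ~ U(0.5, 1.5) and h_c ~ U(0.8, 1.2) channel gains, and per band a
    single frequency f ~ U(low, high) and phase phi shared across channels.
    Markers are placed every ``marker_period`` seconds starting at t = 0.
    """
    if class_label not in config.band_powers:
        raise ValueError(f"class_label {class_label} not in band_powers")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, C, fs = config.n_samples, config.n_channels, config.fs
    t = np.arange(n) / fs

    data = np.zeros((C, n))
    gains = rng.uniform(0.5, 1.5, size=C)
    shared = _colored_noise(rng, n, config.noise_exponent, fs)
    for c in range(C):
        indep = _colored_noise(rng, n, config.noise_exponent, fs)
        data[c] = config.noise_scale * (gains[c] * shared
                                        + config.spatial_noise * indep)

    for name in sorted(config.band_powers[class_label]):
        band = config.band_powers[class_label][name]
        freq = band.low if band.low == band.high else rng.uniform(band.low, band.high)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ch_gain = rng.uniform(0.8, 1.2, size=C)
        if band.amplitude > 0:
            data += band.amplitude * ch_gain[:, None] * np.sin(
                2.0 * np.pi * freq * t + phase)[None, :]

    marker_step = config.marker_period
    marker_samples = np.arange(0.0, config.duration - 1e-9, marker_step) * fs
    markers = [(int(round(s)), 1) for s in marker_samples if round(s) < n]

    return RawRecording(data=data, fs=fs, markers=markers,
                        label=int(class_label), subject=subject)


@dataclass(frozen=True)
class ArtifactSpec:
    """Which artifacts to inject and how strongly.

    ``blink_multiplier`` scales the blink peak relative to the pre-injection
    channel standard deviation; ``blink_channel_ids=None`` targets the first
    quarter of channels (a stand-in for a frontal montage subset).
    ``blink_times_s`` overrides the random (rate-based) placement, which is
    useful when a fixed fraction of epochs must be contaminated.
    """

    blink_rate: float = 0.0            # events per minute
    blink_multiplier: float = 10.0
    blink_duration: float = 0.4        # seconds
    blink_jitter: float = 0.15         # per-channel latency jitter (s)
    blink_channel_ids: Sequence[int] | None = None
    blink_times_s: Sequence[float] | None = None
    line_noise_freq: float | None = None
    line_noise_amplitude: float = 0.0
    flat_channel_ids: Sequence[int] = ()
    noisy_channel_ids: Sequence[int] = ()
    noisy_multiplier: float = 10.0

    def __post_init__(self) -> None:
        for m in (self.blink_multiplier, self.noisy_multiplier,
                  self.line_noise_amplitude):
            if m < 0:
                raise ValueError("artifact multipliers must be >= 0")

    @property
    def empty(self) -> bool:
        return (self.blink_rate == 0 and not self.blink_times_s
                and self.line_noise_freq is None
                and not self.flat_channel_ids and not self.noisy_channel_ids)


@dataclass(frozen=True)
class ArtifactEvent:
    """Ground-truth record of one injected artifact on one channel."""

    kind: str                 # "blink" | "line_noise" | "flat" | "hf_noise"
    channel: int
    start: int                # first affected sample (inclusive)
    stop: int                 # last affected sample (exclusive)


def _check_channels(ids: Sequence[int], n_channels: int, what: str) -> list[int]:
    out = [int(i) for i in ids]
    for i in out:
        if not 0 <= i < n_channels:
            raise ValueError(f"{what} channel id {i} out of range [0, {n_channels})")
    return out


def inject_artifacts(rec: RawRecording, spec: ArtifactSpec,
                     seed: int = 0) -> tuple[RawRecording, list[ArtifactEvent]]:
    """Return a modified copy of ``rec`` plus a log of every injected artifact.

    Blinks are Gaussian-envelope low-frequency transients whose peak equals
    ``blink_multiplier`` times the pre-injection channel standard deviation.
    Flat channels are set exactly constant; noisy channels get additive
    broadband Gaussian noise at ``noisy_multiplier`` times the channel std.
    """
    if rec.n_samples == 0:
        raise ValueError("recording is empty")
    rng = np.random.default_rng(seed)
    out = rec.copy()
    log: list[ArtifactEvent] = []
    C, n, fs = rec.n_channels, rec.n_samples, rec.fs

    # Blinks first, so their amplitude references the clean channel std.
    blink_ch = (list(range(max(1, C // 4)))
                if spec.blink_channel_ids is None
                else _check_channels(spec.blink_channel_ids, C, "blink"))
    if spec.blink_times_s is not None:
        times = list(spec.blink_times_s)
    elif spec.blink_rate > 0:
        n_blinks = int(round(spec.blink_rate * rec.duration / 60.0))
        half = spec.blink_duration / 2.0
        times = sorted(rng.uniform(half, rec.duration - half, size=n_blinks))
    else:
        times = []
    if times:
        width = int(round(spec.blink_duration * fs))
        base_std = out.data.std(axis=1)
        for t0 in times:
            for c in blink_ch:
                # Per-channel latency jitter: the transient propagates across
                # the montage rather than arriving as one scaled template.
                center = int(round((t0 + rng.uniform(-spec.blink_jitter,
                                                     spec.blink_jitter)) * fs))
                lo, hi = max(0, center - width // 2), min(n, center + width // 2)
                if hi <= lo:
                    continue
                tt = np.arange(lo, hi)
                bump = np.exp(-0.5 * ((tt - center) / (width / 6.0)) ** 2)
                out.data[c, lo:hi] += spec.blink_multiplier * base_std[c] * bump
                log.append(ArtifactEvent("blink", c, lo, hi))

    if spec.line_noise_freq is not None and spec.line_noise_amplitude > 0:
        t = np.arange(n) / fs
        hum = spec.line_noise_amplitude * np.sin(2 * np.pi * spec.line_noise_freq * t)
        out.data += hum[None, :]
        for c in range(C):
            log.append(ArtifactEvent("line_noise", c, 0, n))

    for c in _check_channels(spec.noisy_channel_ids, C, "noisy"):
        out.data[c] += spec.noisy_multiplier * out.data[c].std() * rng.standard_normal(n)
        log.append(ArtifactEvent("hf_noise", c, 0, n))

    for c in _check_channels(spec.flat_channel_ids, C, "flat"):
        out.data[c] = out.data[c].mean()
        log.append(ArtifactEvent("flat", c, 0, n))

    return out, log


def generate_dataset(config: SynthConfig) -> list[tuple[RawRecording, int]]:
    """Balanced two-class cohort; per-recording seeds spawn from the master seed."""
    if config.n_subjects_per_class < 1:
        raise ValueError("n_subjects_per_class must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_subjects_per_class)
    out: list[tuple[RawRecording, int]] = []
    k = 0
    for label in (0, 1):
        for i in range(config.n_subjects_per_class):
            rec = generate_recording(config, label, seed=children[k],
                                     subject=f"S{label}{i:03d}")
            out.append((rec, label))
            k += 1
    return out


def write_dataset(dataset: list[tuple[RawRecording, int]],
                  out_dir: str | Path) -> Path:
    """Write one EDF per recording plus a TSV sidecar of labels; returns the TSV path."""
    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["filename\tsubject\tlabel"]
    for i, (rec, label) in enumerate(dataset):
        name = f"{rec.subject or f'rec{i:03d}'}.edf"
        write_edf(rec, out_dir / name)
        rows.append(f"{name}\t{rec.subject or ''}\t{label}")
    tsv = out_dir / "labels.tsv"
    tsv.write_text("\n".join(rows) + "\n")
    return tsv
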