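"""Core in-memory containers shared by the pipeline stages.

All containers are plain dataclasses over numpy arrays: a continuous
multichannel recording, an epoched view of it, and spectral densities.
Arrays are owned (copied on construction where mutation would surprise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RawRecording",
    "EpochSet",
    "SpectralDensity",
    "load_epochs",
]


@dataclass
class RawRecording:
    """Continuous multichannel EEG: ``data`` is channels x samples.

    ``markers`` are (sample_index, marker_id) event anchors; ``filtered``
    is a provenance flag set by the bandpass stage.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    markers: list[tuple[int, int]] = field(default_factory=list)
    filtered: bool = False
    label: int | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        n = self.data.shape[1]
        for s, _ in self.markers:
            if not 0 <= s < n:
                raise ValueError(f"marker sample {s} outside recording of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy(), markers=list(self.markers),
                       channel_labels=list(self.channel_labels))


@dataclass
class EpochSet:
    """Epochs x channels x samples, with per-epoch labels and rejection flags.

    Rejected epochs are flagged, never deleted, so cleaning is auditable.
    """

    data: np.ndarray
    fs: float
    tmin: float
    tmax: float
    labels: np.ndarray | None = None
    rejected: np.ndarray | None = None
    reject_reasons: list[str] = field(default_factory=list)
    subject: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if self.tmin >= self.tmax:
            raise ValueError("tmin must be < tmax")
        expect = int(round((self.tmax - self.tmin) * self.fs))
        if self.data.shape[2] != expect:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != (tmax-tmin)*fs = {expect}")
        n = self.data.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per epoch")
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if not self.reject_reasons:
            self.reject_reasons = [""] * n

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def retained(self) -> np.ndarray:
        """Indices of epochs that survived cleaning."""
        return np.flatnonzero(~self.rejected)

    def save(self, path: str | Path) -> None:
        """Write the epoch array (npy) plus a JSON metadata sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        meta = {
            "fs": self.fs, "tmin": self.tmin, "tmax": self.tmax,
            "labels": None if self.labels is None else self.labels.tolist(),
            "rejected": self.rejected.tolist(),
            "reject_reasons": self.reject_reasons,
            "subject": self.subject,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        data=data, fs=meta["fs"], tmin=meta["tmin"], tmax=meta["tmax"],
        labels=None if meta["labels"] is None else np.array(meta["labels"]),
        rejected=np.array(meta["rejected"], dtype=bool),
        reject_reasons=meta["reject_reasons"], subject=meta["subject"],
    )


@dataclass
class SpectralDensity:
    """Power spectral density per epoch and channel: power is (epochs, channels, freqs)."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape[-1] != self.freqs.shape[0]:
            raise ValueError("last power axis must match frequency grid")
        if np.any(self.power < -1e-12):
            raise ValueError("PSD must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]
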