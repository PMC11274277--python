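"""Minimal EDF+C file I/O.

Writing implements the 16-bit EDF+ continuous format directly (header,
per-signal headers, one annotation signal carrying the event markers as
time-stamped annotation lists). Reading goes through MNE, which is also
the natural independent check that the files we emit are standard.
Physical units are microvolts; sampling rates must be integer Hz and
recordings an integer number of seconds (records are 1 s long).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import RawRecording

__all__ = ["write_edf", "read_edf"]

_ANN_SAMPLES_PER_RECORD = 60  # 120 bytes of TAL space per 1 s record


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long for EDF header: {text!r}")
    return b.ljust(width)


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a RawRecording to an EDF+C file, markers as annotations."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples / fs
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError("EDF export requires an integer number of seconds")
    n_records = int(round(n_records))
    C = rec.n_channels
    ns = C + 1  # data channels + annotation channel

    # Symmetric physical range per channel; 1.0 guards an all-zero channel.
    phys_max = np.maximum(np.abs(rec.data).max(axis=1) * 1.0000001, 1.0)
    digital = np.round(rec.data / phys_max[:, None] * 32767.0).astype("<i2")

    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad("X X X X", 80)
    hdr += _pad("Startdate 01-JAN-2000 X X X", 80)
    hdr += _pad("01.01.00", 8)
    hdr += _pad("00.00.00", 8)
    hdr += _pad(str(256 * (ns + 1)), 8)
    hdr += _pad("EDF+C", 44)
    hdr += _pad(str(n_records), 8)
    hdr += _pad("1", 8)
    hdr += _pad(str(ns), 4)

    labels = [lab[:16] for lab in rec.channel_labels] + ["EDF Annotations"]
    hdr += b"".join(_pad(lab, 16) for lab in labels)
    hdr += b"".join(_pad("", 80) for _ in range(ns))                      # transducer
    hdr += b"".join(_pad("uV", 8) for _ in range(C)) + _pad("", 8)        # phys dim
    hdr += b"".join(_pad(f"{-m:.6g}"[:8], 8) for m in phys_max) + _pad("-1", 8)
    hdr += b"".join(_pad(f"{m:.6g}"[:8], 8) for m in phys_max) + _pad("1", 8)
    hdr += b"".join(_pad("-32768", 8) for _ in range(ns))
    hdr += b"".join(_pad("32767", 8) for _ in range(ns))
    hdr += b"".join(_pad("", 80) for _ in range(ns))                      # prefiltering
    hdr += b"".join(_pad(str(fs), 8) for _ in range(C))
    hdr += _pad(str(_ANN_SAMPLES_PER_RECORD), 8)
    hdr += b"".join(_pad("", 32) for _ in range(ns))

    # Quantize marker onsets to sample times; group by 1 s record.
    markers_by_record: dict[int, list[tuple[float, int]]] = {}
    for sample, mid in rec.markers:
        onset = sample / fs
        markers_by_record.setdefault(int(onset), []).append((onset, mid))

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for onset, mid in markers_by_record.get(r, []):
                tal += f"+{onset:.6g}\x14{mid}\x14\x00".encode("ascii")
            room = 2 * _ANN_SAMPLES_PER_RECORD
            if len(tal) > room:
                raise ValueError("too many markers in one second for TAL buffer")
            fh.write(tal.ljust(room, b"\x00"))
    return path


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF/EDF+ file via MNE; annotations become integer markers."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    fs = float(raw.info["sfreq"])
    markers: list[tuple[int, int]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        try:
            mid = int(float(desc))
        except ValueError:
            mid = 1
        markers.append((int(round(onset * fs)), mid))
    markers.sort()
    return RawRecording(data=data, fs=fs, channel_labels=list(raw.ch_names),
                        markers=markers)
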