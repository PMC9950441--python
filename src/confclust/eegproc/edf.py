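"""Minimal EDF (European Data Format) reader/writer.

Supports the plain EDF subset needed here: identical sampling rate per signal,
16-bit samples, no annotations.  Implemented directly because no EDF library
is guaranteed in the runtime environment; the format is a fixed-width ASCII
header followed by little-endian int16 data records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording: channels x samples, microvolts."""

    data: np.ndarray
    fs: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: ContinuousRecording, record_duration: float = 1.0) -> None:
    """Write a recording as plain EDF (one data record per ``record_duration`` s)."""
    n_sig = len(rec.channels)
    spr = int(round(rec.fs * record_duration))
    if spr <= 0:
        raise ValueError("record duration too short for sampling rate")
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    phys_min = np.floor(padded.min(axis=1)) - 1.0
    phys_max = np.ceil(padded.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field("synthetic", 80))
        f.write(_field("confclust", 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(256 + 256 * n_sig, 8))
        f.write(_field("", 44))
        f.write(_field(n_rec, 8))
        f.write(_field(f"{record_duration:g}", 8))
        f.write(_field(n_sig, 4))
        for ch in rec.channels:
            f.write(_field(ch, 16))
        for _ in rec.channels:
            f.write(_field("AgAgCl electrode", 80))
        for _ in rec.channels:
            f.write(_field("uV", 8))
        for v in phys_min:
            f.write(_field(f"{v:g}", 8))
        for v in phys_max:
            f.write(_field(f"{v:g}", 8))
        for _ in rec.channels:
            f.write(_field(dig_min, 8))
        for _ in rec.channels:
            f.write(_field(dig_max, 8))
        for _ in rec.channels:
            f.write(_field("", 80))
        for _ in rec.channels:
            f.write(_field(spr, 8))
        for _ in rec.channels:
            f.write(_field("", 32))

        scale = (phys_max - phys_min) / (dig_max - dig_min)
        for r in range(n_rec):
            block = padded[:, r * spr : (r + 1) * spr]
            digital = np.round((block - phys_min[:, None]) / scale[:, None]) + dig_min
            digital = np.clip(digital, dig_min, dig_max).astype("<i2")
            f.write(digital.tobytes())


def read_edf(path) -> ContinuousRecording:
    """Read a plain EDF file into a ContinuousRecording (microvolts)."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise ValueError("truncated EDF header")
        n_rec = int(header[236:244].decode("ascii").strip())
        record_duration = float(header[244:252].decode("ascii").strip())
        n_sig = int(header[252:256].decode("ascii").strip())

        sig_header = f.read(256 * n_sig)

        def sig_fields(offset: int, width: int) -> list[str]:
            start = offset * n_sig
            return [
                sig_header[start + i * width : start + (i + 1) * width]
                .decode("ascii")
                .strip()
                for i in range(n_sig)
            ]

        labels = sig_fields(0, 16)
        phys_min = np.array([float(v) for v in sig_fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in sig_fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in sig_fields(16 + 80 + 8 + 32 + 80, 8)]

        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal sampling rates are not supported")
        samples_per_record = spr[0]
        fs = samples_per_record / record_duration

        raw = np.frombuffer(f.read(), dtype="<i2")

    expected = n_rec * n_sig * samples_per_record
    raw = raw[:expected].reshape(n_rec, n_sig, samples_per_record)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (raw - dig_min[None, :, None]) * scale[None, :, None] + phys_min[None, :, None]
    data = np.transpose(data, (1, 0, 2)).reshape(n_sig, -1)
    return ContinuousRecording(data=data, fs=fs, channels=labels)
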