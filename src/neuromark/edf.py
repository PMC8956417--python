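"""Minimal EDF (European Data Format) codec.

Writes and reads plain EDF files: ASCII headers, 16-bit little-endian data
records. Enough of the format for round-tripping multichannel EEG with
physical units in microvolts; no EDF+ annotations, no discontinuous records.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["write_edf", "read_edf", "EdfSignals"]

_HDR = 256  # bytes for the fixed header and per-signal header block


def _pad(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


@dataclass
class EdfSignals:
    """Decoded EDF content: samples in physical units (uV for EEG)."""

    samples: np.ndarray  # channels x time, float64
    labels: list[str]
    fs: float
    recording_id: str


def write_edf(
    path: str | os.PathLike,
    samples: np.ndarray,
    labels: list[str],
    fs: float,
    recording_id: str = "",
    physical_dim: str = "uV",
) -> None:
    """Write ``samples`` (channels x time, physical units) as plain EDF.

    Uses 1 s data records; the recording length must be an integer number of
    seconds. Quantization is 16 bit over a symmetric physical range derived
    from the data, so round-trip error is bounded by range/65535. Header
    dates are fixed constants, which keeps output byte-reproducible.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be channels x time")
    ns, nt = samples.shape
    if len(labels) != ns:
        raise ValueError(f"{ns} channels but {len(labels)} labels")
    spr = round(fs)  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    if nt % spr != 0:
        raise ValueError("recording length must be a whole number of seconds")
    n_records = nt // spr

    # symmetric physical range per channel, padded to avoid clipping
    absmax = np.maximum(np.abs(samples).max(axis=1), 1e-6)
    pmax = np.array([float(f"{v:.6g}") for v in absmax * 1.0001])
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))  # local patient id (anonymous)
        fh.write(_pad(recording_id[:80], 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(_HDR * (1 + ns)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))  # record duration, seconds
        fh.write(_pad(str(ns), 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in labels:
            fh.write(_pad("synthetic EEG", 80))
        for _ in labels:
            fh.write(_pad(physical_dim, 8))
        for v in pmax:
            fh.write(_pad(f"{-v:.6g}", 8))
        for v in pmax:
            fh.write(_pad(f"{v:.6g}", 8))
        for _ in labels:
            fh.write(_pad(str(dig_min), 8))
        for _ in labels:
            fh.write(_pad(str(dig_max), 8))
        for _ in labels:
            fh.write(_pad("", 80))  # prefiltering
        for _ in labels:
            fh.write(_pad(str(spr), 8))
        for _ in labels:
            fh.write(_pad("", 32))  # reserved

        scale = (dig_max - dig_min) / (2 * pmax)
        digital = np.rint((samples + pmax[:, None]) * scale[:, None] + dig_min)
        digital = np.clip(digital, dig_min, dig_max).astype("<i2")
        # record-major layout: for each 1 s record, all channels in sequence
        rec = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())


def read_edf(path: str | os.PathLike) -> EdfSignals:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise ValueError(f"truncated EDF file (header): {path}")

        def fixed(lo: int, hi: int) -> str:
            return head[lo:hi].decode("ascii", "replace").strip()

        recording_id = fixed(88, 168)
        header_bytes = int(fixed(184, 192))
        n_records = int(fixed(236, 244))
        record_dur = float(fixed(244, 252))
        ns = int(fixed(252, 256))

        sig_head = fh.read(_HDR * ns)
        if len(sig_head) < _HDR * ns:
            raise ValueError(f"truncated EDF file (signal headers): {path}")

        def col(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width: base + (i + 1) * width]
                .decode("ascii", "replace").strip()
                for i in range(ns)
            ]

        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in col(16 + 80 + 8 + 4 * 8 + 80, 8)]

        if len(set(spr)) != 1:
            raise ValueError("read_edf supports a single sampling rate for all signals")
        fs = spr[0] / record_dur

        expected = header_bytes + 2 * n_records * sum(spr)
        if size < expected:
            raise ValueError(
                f"truncated EDF file: {path} ({size} bytes, expected {expected})"
            )
        raw = np.frombuffer(fh.read(2 * n_records * sum(spr)), dtype="<i2")

    rec = raw.reshape(n_records, ns, spr[0])
    digital = rec.transpose(1, 0, 2).reshape(ns, n_records * spr[0]).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return EdfSignals(samples=physical, labels=labels, fs=fs, recording_id=recording_id)
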