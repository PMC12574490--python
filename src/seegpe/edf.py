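"""Minimal 16-bit EDF writing and header probing.

Writing emits plain continuous EDF (one second per data record when the
sampling rate is integral, a single record otherwise); event markers travel in
the sidecar TSV format instead of an embedded annotations channel.  Reading of
full recordings goes through MNE; this module only parses the fixed-layout
ASCII header, which MNE does not expose, to validate per-signal sampling rates
before loading.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # Shortest exact-enough decimal that fits the fixed-width field.
    for fmt in (f"{value:g}", f"{value:.5f}", f"{value:.2f}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"value {value} does not fit an EDF field of width {width}")


def write_edf(samples: np.ndarray, rate_hz: float, labels: list[str], path) -> None:
    """Write a channels x time array of physical values (µV) as 16-bit EDF.

    Physical min/max are symmetric per channel and cover the signal range, so
    round-trip error is at most one quantization step
    ((pmax - pmin) / 65535 per channel).
    """
    data = np.asarray(samples, dtype=float)
    if data.ndim != 2 or data.size == 0:
        raise ValueError("recording is empty; nothing to write")
    if len(labels) != data.shape[0]:
        raise ValueError("label count must equal channel count")
    n_chan, n_samples = data.shape

    if abs(rate_hz - round(rate_hz)) < 1e-9 and n_samples % int(round(rate_hz)) == 0:
        spr = int(round(rate_hz))           # 1-s data records
        record_dur = 1.0
        n_records = n_samples // spr
    else:
        spr = n_samples                      # everything in one record
        record_dur = n_samples / rate_hz
        n_records = 1

    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    pmax = np.array([float(f"{v:.6g}") for v in pmax * 1.0000001])  # header-exact bounds
    gain = 2.0 * pmax / (_DIG_MAX - _DIG_MIN)
    digital = np.clip(np.round(data / gain[:, None]), _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),                      # version
            _ascii("X X X X", 80),               # patient id (anonymous)
            _ascii("Startdate X X X X", 80),     # recording id
            _ascii("01.01.00", 8),               # start date
            _ascii("00.00.00", 8),               # start time
            _ascii(256 + 256 * n_chan, 8),       # header length
            _ascii("", 44),                      # reserved
            _ascii(n_records, 8),
            _num(record_dur, 8),
            _ascii(n_chan, 4),
        ]
    )
    fields = [
        b"".join(_ascii(lab, 16) for lab in labels),
        b"".join(_ascii("", 80) for _ in labels),                    # transducer
        b"".join(_ascii("uV", 8) for _ in labels),                   # physical dim
        b"".join(_num(-p, 8) for p in pmax),
        b"".join(_num(p, 8) for p in pmax),
        b"".join(_ascii(_DIG_MIN, 8) for _ in labels),
        b"".join(_ascii(_DIG_MAX, 8) for _ in labels),
        b"".join(_ascii("", 80) for _ in labels),                    # prefiltering
        b"".join(_ascii(spr, 8) for _ in labels),
        b"".join(_ascii("", 32) for _ in labels),                    # reserved
    ]
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for f in fields:
                fh.write(f)
            # records: channel-major within each record
            for r in range(n_records):
                fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    except OSError as err:
        raise IOError(f"cannot write EDF file {path}: {err}") from err


@dataclass
class EdfHeaderInfo:
    n_channels: int
    labels: list[str]
    rates_hz: list[float]
    record_dur_s: float
    n_records: int


def probe_header(path) -> EdfHeaderInfo:
    """Parse the EDF fixed header; raises IOError on truncated/invalid files."""
    try:
        size = os.path.getsize(path)
        with open(path, "rb") as fh:
            head = fh.read(256)
            if len(head) < 256:
                raise IOError(f"truncated EDF file: {path}")
            try:
                n_records = int(head[236:244].decode("ascii").strip())
                record_dur = float(head[244:252].decode("ascii").strip())
                ns = int(head[252:256].decode("ascii").strip())
            except (UnicodeDecodeError, ValueError) as err:
                raise IOError(f"not a valid EDF header: {path} ({err})") from err
            sig = fh.read(256 * ns)
            if len(sig) < 256 * ns:
                raise IOError(f"truncated EDF file: {path}")
    except OSError as err:
        raise IOError(f"cannot read EDF file {path}: {err}") from err

    def field(block: int, width: int) -> list[str]:
        base = sum(w * ns for w in (16, 80, 8, 8, 8, 8, 8, 80, 8, 32)[:block])
        return [
            sig[base + i * width : base + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(ns)
        ]

    labels = field(0, 16)
    spr = [int(v) for v in field(8, 8)]
    if record_dur <= 0:
        raise IOError(f"invalid record duration in {path}")
    rates = [n / record_dur for n in spr]
    expected = 256 + 256 * ns + n_records * sum(spr) * 2
    if size < expected:
        raise IOError(f"truncated EDF file: {path} ({size} bytes, expected {expected})")
    return EdfHeaderInfo(
        n_channels=ns, labels=labels, rates_hz=rates, record_dur_s=record_dur, n_records=n_records
    )
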