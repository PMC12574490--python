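"""Shared fixtures and the independent brute-force ordinal-pattern oracle.

The oracle deliberately shares no code with the package: patterns come from
``sorted`` with an explicit (value, index) key, counting from ``Counter``,
entropy from ``math``.  It is the reference the optimized implementation is
checked against.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from seegpe.edf import _DIG_MAX, _DIG_MIN, _ascii, _num


def brute_force_patterns(series, D, tau):
    """Ordinal-pattern counts by direct enumeration with the temporal tie rule."""
    x = list(series)
    counts = Counter()
    for start in range(len(x) - (D - 1) * tau):
        vec = [x[start + k * tau] for k in range(D)]
        pattern = tuple(sorted(range(D), key=lambda i: (vec[i], i)))
        counts[pattern] += 1
    return counts


def brute_force_pe(series, D, tau):
    """Normalized permutation entropy from the brute-force counts."""
    counts = brute_force_patterns(series, D, tau)
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(D))


@pytest.fixture(scope="session")
def default_simulation():
    """One simulated seizure at generator defaults, shared across tests."""
    from seegpe import SimulationParams, simulate_seizure_recording

    params = SimulationParams(n_channels=4, seed=1)
    return params, simulate_seizure_recording(params)


def write_edf_with_annotations(path, data, rate, labels=None):
    """Craft an EDF+ file with a trailing 'EDF Annotations' channel."""
    data = np.asarray(data, dtype=float)
    n_chan, n_samples = data.shape
    labels = labels or [f"B{i + 1}" for i in range(n_chan)]
    spr = int(rate)
    n_records = n_samples // spr
    all_labels = labels + ["EDF Annotations"]
    ns = n_chan + 1
    annot_spr = 30
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.0000001
    gain = 2 * pmax / (_DIG_MAX - _DIG_MIN)
    dig = np.clip(np.round(data / gain[:, None]), _DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(
            _ascii("0", 8) + _ascii("X X X X", 80) + _ascii("Startdate X X X X", 80)
            + _ascii("01.01.00", 8) + _ascii("00.00.00", 8) + _ascii(256 + 256 * ns, 8)
            + _ascii("EDF+C", 44) + _ascii(n_records, 8) + _num(1.0, 8) + _ascii(ns, 4)
        )
        fh.write(b"".join(_ascii(lab, 16) for lab in all_labels))
        fh.write(b"".join(_ascii("", 80) for _ in all_labels))
        fh.write(b"".join(_ascii("uV", 8) for _ in range(n_chan)) + _ascii("", 8))
        fh.write(b"".join(_num(-p, 8) for p in pmax) + _num(-1, 8))
        fh.write(b"".join(_num(p, 8) for p in pmax) + _num(1, 8))
        fh.write(b"".join(_ascii(_DIG_MIN, 8) for _ in all_labels))
        fh.write(b"".join(_ascii(_DIG_MAX, 8) for _ in all_labels))
        fh.write(b"".join(_ascii("", 80) for _ in all_labels))
        fh.write(b"".join(_ascii(spr, 8) for _ in range(n_chan)) + _ascii(annot_spr, 8))
        fh.write(b"".join(_ascii("", 32) for _ in all_labels))
        for r in range(n_records):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())
            tal = f"+{r}\x14\x14\x00".encode()
            fh.write(tal + b"\x00" * (annot_spr * 2 - len(tal)))
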