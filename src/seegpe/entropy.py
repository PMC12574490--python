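"""Ordinal patterns and normalized permutation entropy over sliding windows.

Permutation entropy (PE) quantifies the complexity of a time series as the
Shannon entropy of its distribution of rank-order (ordinal) patterns.  Each
length-``D`` embedding vector ``(x[t], x[t+tau], ..., x[t+(D-1)*tau])`` is
mapped to the permutation of indices that sorts it ascending; the entropy of
the pattern frequencies, normalized by ``log(D!)``, lies in ``[0, 1]`` — 0 for
a perfectly regular (single-pattern) series, 1 for a fully random one.

The windowed variant slides a fixed-length window over a multichannel
recording and yields one PE value per channel and window, the substrate for
all downstream seizure-complexity statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PEParams",
    "WindowingParams",
    "OrdinalPatternDistribution",
    "EntropyMatrix",
    "ordinal_pattern",
    "pattern_distribution",
    "permutation_entropy",
    "sliding_window_pe",
    "global_entropy_curve",
]


@dataclass(frozen=True)
class PEParams:
    """Embedding parameters: dimension ``D`` (samples per vector) and delay ``tau``."""

    D: int = 3
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.D) != self.D or self.D < 2:
            raise ValueError(f"embedding dimension D must be an integer >= 2, got {self.D}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"time delay tau must be an integer >= 1, got {self.tau}")

    @property
    def span(self) -> int:
        """Number of samples covered by one embedding vector."""
        return (self.D - 1) * self.tau + 1


@dataclass(frozen=True)
class WindowingParams:
    """Sliding-window geometry in seconds (default 5-s windows, 2.5-s hop)."""

    window_s: float = 5.0
    step_s: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.window_s):
            raise ValueError(
                f"require 0 < step_s <= window_s, got step_s={self.step_s}, window_s={self.window_s}"
            )

    def in_samples(self, rate_hz: float) -> tuple[int, int]:
        """Window and step lengths in samples (seconds rounded half up)."""
        w = int(math.floor(self.window_s * rate_hz + 0.5))
        s = int(math.floor(self.step_s * rate_hz + 0.5))
        return w, s


@dataclass
class OrdinalPatternDistribution:
    counts: dict[tuple[int, ...], int]
    n_vectors: int

    def probabilities(self) -> np.ndarray:
        return np.array([c / self.n_vectors for c in self.counts.values()])


def ordinal_pattern(vector) -> tuple[int, ...]:
    """Ordinal pattern of one embedding vector.

    Returns the permutation of ``0..D-1`` that sorts the vector ascending.
    Equal values are ranked by temporal order (the earlier sample ranks
    lower), the classic Bandt-Pompe tie convention, so the result is
    deterministic: ``(5, 5, 1) -> (2, 0, 1)``.
    """
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"expected a 1-D vector of length >= 2, got shape {v.shape}")
    return tuple(int(i) for i in np.argsort(v, kind="stable"))


def _pattern_codes(series: np.ndarray, params: PEParams) -> np.ndarray:
    """Integer pattern code for every embedding vector of the series.

    Codes are base-``D`` digit strings of the argsort permutation; distinct
    permutations map to distinct codes.  Vectorized over all vector starts.
    """
    D, tau = params.D, params.tau
    n = series.size - (D - 1) * tau
    idx = np.arange(n)[:, None] + np.arange(D)[None, :] * tau
    perms = np.argsort(series[idx], axis=1, kind="stable")
    return perms @ (D ** np.arange(D))


def _check_length(series: np.ndarray, params: PEParams) -> None:
    need = params.span
    if series.size < need:
        raise ValueError(
            f"series of length {series.size} too short for D={params.D}, tau={params.tau}; "
            f"need at least {need} samples"
        )


def pattern_distribution(series, params: PEParams = PEParams()) -> OrdinalPatternDistribution:
    """Count ordinal patterns over all ``N - (D-1)*tau`` embedding vectors."""
    x = np.asarray(series, dtype=float)
    _check_length(x, params)
    codes = _pattern_codes(x, params)
    uniq, counts = np.unique(codes, return_counts=True)
    D = params.D
    digits = (uniq[:, None] // (D ** np.arange(D))) % D
    patterns = {tuple(int(d) for d in row): int(c) for row, c in zip(digits, counts)}
    return OrdinalPatternDistribution(counts=patterns, n_vectors=int(codes.size))


def _entropy_from_counts(counts: np.ndarray, n_patterns: int) -> float:
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(n_patterns)


def permutation_entropy(series, params: PEParams = PEParams()) -> float:
    """Normalized permutation entropy of a 1-D series, in ``[0, 1]``."""
    x = np.asarray(series, dtype=float)
    _check_length(x, params)
    if not np.isfinite(x).all():
        return float("nan")
    codes = _pattern_codes(x, params)
    counts = np.bincount(codes, minlength=params.D ** params.D).astype(float)
    return _entropy_from_counts(counts, math.factorial(params.D))


@dataclass
class EntropyMatrix:
    """Channels x windows matrix of normalized PE with window time stamps."""

    values: np.ndarray
    window_centers_s: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_centers_s = np.asarray(self.window_centers_s, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D channels x windows array")
        if self.values.shape[1] != self.window_centers_s.size:
            raise ValueError("window_centers_s length must equal the number of windows")
        if self.channel_labels and len(self.channel_labels) != self.values.shape[0]:
            raise ValueError("channel_labels length must equal the number of channels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("finite PE values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        """Serialize as CSV: first column window_center_s, one column per channel."""
        labels = self.channel_labels or [f"ch{i}" for i in range(self.n_channels)]
        df = pd.DataFrame(self.values.T, columns=labels)
        df.insert(0, "window_center_s", self.window_centers_s)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EntropyMatrix":
        df = pd.read_csv(path, float_precision="round_trip")  # bit-exact reload
        if "window_center_s" not in df.columns:
            raise ValueError(f"{path}: missing required column 'window_center_s'")
        centers = df.pop("window_center_s").to_numpy(dtype=float)
        return cls(
            values=df.to_numpy(dtype=float).T,
            window_centers_s=centers,
            channel_labels=list(df.columns),
        )


def sliding_window_pe(
    recording,
    pe_params: PEParams = PEParams(),
    win: WindowingParams = WindowingParams(),
) -> EntropyMatrix:
    """Windowed PE of a multichannel recording.

    Windows start at t = 0 and advance by ``step_s``; trailing samples that do
    not fill a window are dropped.  The embedding runs within each window
    independently.  Any non-finite sample inside a window makes that window's
    PE non-finite for that channel (missing signal is never interpolated).
    """
    rate = recording.sampling_rate_hz
    data = np.asarray(recording.samples, dtype=float)
    w_samp, s_samp = win.in_samples(rate)
    if w_samp < pe_params.span + 1:
        raise ValueError(
            f"window of {w_samp} samples shorter than the minimum embedding length "
            f"{pe_params.span + 1} for D={pe_params.D}, tau={pe_params.tau}"
        )
    n_samples = data.shape[1]
    if n_samples < w_samp:
        raise ValueError(f"recording of {n_samples} samples shorter than one window ({w_samp})")
    n_windows = (n_samples - w_samp) // s_samp + 1
    centers = np.arange(n_windows) * win.step_s + win.window_s / 2.0

    n_patterns = math.factorial(pe_params.D)
    code_span = pe_params.D ** pe_params.D
    values = np.full((data.shape[0], n_windows), np.nan)
    vecs_per_window = w_samp - (pe_params.D - 1) * pe_params.tau
    for ch in range(data.shape[0]):
        x = data[ch]
        finite = np.isfinite(x)
        codes = _pattern_codes(np.where(finite, x, 0.0), pe_params) if finite.any() else None
        for k in range(n_windows):
            lo = k * s_samp
            if not finite[lo : lo + w_samp].all():
                continue
            counts = np.bincount(codes[lo : lo + vecs_per_window], minlength=code_span).astype(float)
            values[ch, k] = _entropy_from_counts(counts, n_patterns)
    return EntropyMatrix(
        values=values,
        window_centers_s=centers,
        channel_labels=list(recording.labels),
    )


def global_entropy_curve(matrix: EntropyMatrix) -> np.ndarray:
    """Mean complexity across channels per window (the 'global entropy curve').

    Unweighted mean over channels, ignoring non-finite entries; a window with
    no finite channel yields NaN.
    """
    if matrix.n_channels == 0 or matrix.n_windows == 0:
        raise ValueError("cannot average an empty entropy matrix")
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix.values, axis=0)
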