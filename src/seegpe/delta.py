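"""Event-based segmentation of the entropy matrix and the Delta-Entropy statistic.

Delta Entropy (ΔE) contrasts the deepest complexity loss during a seizure
with the pre-stimulation reference level: per bipolar channel,

    ΔE = mean baseline PE - minimum ictal PE          (drop convention)

where the baseline is the 7 s immediately before the stimulated contacts were
disconnected from the recording (the ``baseline_end`` marker) and the ictal
period is bounded by the ``seizure_onset`` / ``seizure_offset`` markers.
A larger ΔE means a deeper loss of signal complexity.  The literal
"minimum ictal minus mean baseline" reading is available as a sign switch;
every serialized profile records which convention produced it.

Windows are assigned to periods by their center time: baseline windows have
centers in ``[baseline_end - baseline_dur, baseline_end)`` (right-open — the
marker itself starts the artifacted disconnection epoch), ictal windows in
``[seizure_onset, seizure_offset]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EntropyMatrix
from .io import EventTimeline

__all__ = [
    "SegmentationParams",
    "DeltaEntropyProfile",
    "segment_windows",
    "compute_delta_entropy",
]


@dataclass(frozen=True)
class SegmentationParams:
    baseline_dur_s: float = 7.0

    def __post_init__(self) -> None:
        if self.baseline_dur_s <= 0:
            raise ValueError(f"baseline_dur_s must be positive, got {self.baseline_dur_s}")


def segment_windows(
    matrix: EntropyMatrix,
    timeline: EventTimeline,
    params: SegmentationParams = SegmentationParams(),
    exclude_labels: tuple[str, ...] = (),
) -> dict[str, np.ndarray]:
    """Label window indices as baseline / ictal / other by window-center containment.

    ``exclude_labels`` optionally removes ictal windows whose centers fall
    inside any event interval with one of those labels (e.g. ``("stim_on",)``
    for a sensitivity analysis excluding the inducing stimulation); windows
    overlapping pulvinar pulses are part of the measured effect and stay in.
    """
    for marker in ("baseline_end", "seizure_onset", "seizure_offset"):
        try:
            timeline.onset_of(marker)
        except KeyError:
            raise ValueError(f"timeline is missing the required marker {marker!r}") from None
    t_base = timeline.onset_of("baseline_end")
    t_on = timeline.onset_of("seizure_onset")
    t_off = timeline.onset_of("seizure_offset")
    if t_off <= t_on:
        raise ValueError(f"seizure_offset ({t_off}) must be after seizure_onset ({t_on})")

    centers = matrix.window_centers_s
    baseline = (centers >= t_base - params.baseline_dur_s) & (centers < t_base)
    ictal = (centers >= t_on) & (centers <= t_off)
    for ev in timeline.events:
        if ev.label in exclude_labels:
            ictal &= ~((centers >= ev.onset_s) & (centers <= ev.onset_s + ev.duration_s))
    if not baseline.any():
        raise ValueError(
            f"no windows centered in the baseline interval "
            f"[{t_base - params.baseline_dur_s:g}, {t_base:g})"
        )
    if not ictal.any():
        raise ValueError(f"no windows centered in the ictal interval [{t_on:g}, {t_off:g}]")
    other = ~(baseline | ictal)
    return {
        "baseline": np.flatnonzero(baseline),
        "ictal": np.flatnonzero(ictal),
        "other": np.flatnonzero(other),
    }


@dataclass
class DeltaEntropyProfile:
    """Per-channel ΔE for one seizure, with segment bookkeeping."""

    channel_labels: list[str]
    baseline_mean: np.ndarray
    ictal_min: np.ndarray
    n_baseline_windows: int
    n_ictal_windows: int
    sign: str = "drop"  # 'drop': baseline - min; 'literal': min - baseline
    delta_e: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.ictal_min = np.asarray(self.ictal_min, dtype=float)
        if not (len(self.channel_labels) == self.baseline_mean.size == self.ictal_min.size):
            raise ValueError("per-channel arrays must match channel_labels in length")
        if self.n_baseline_windows < 1 or self.n_ictal_windows < 1:
            raise ValueError("profiles require at least one baseline and one ictal window")
        if self.sign not in ("drop", "literal"):
            raise ValueError(f"sign must be 'drop' or 'literal', got {self.sign!r}")
        diff = self.baseline_mean - self.ictal_min
        self.delta_e = diff if self.sign == "drop" else -diff

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "channel": self.channel_labels,
                "baseline_mean": self.baseline_mean,
                "ictal_min": self.ictal_min,
                "delta_e": self.delta_e,
            }
        )
        df.attrs["sign"] = self.sign
        with open(path, "w") as fh:
            fh.write(
                f"# sign={self.sign} n_baseline_windows={self.n_baseline_windows} "
                f"n_ictal_windows={self.n_ictal_windows}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "DeltaEntropyProfile":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh, float_precision="round_trip")
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        return cls(
            channel_labels=[str(c) for c in df["channel"]],
            baseline_mean=df["baseline_mean"].to_numpy(),
            ictal_min=df["ictal_min"].to_numpy(),
            n_baseline_windows=int(meta["n_baseline_windows"]),
            n_ictal_windows=int(meta["n_ictal_windows"]),
            sign=meta["sign"],
        )


def compute_delta_entropy(
    matrix: EntropyMatrix,
    timeline: EventTimeline,
    params: SegmentationParams = SegmentationParams(),
    sign: str = "drop",
    exclude_labels: tuple[str, ...] = (),
) -> DeltaEntropyProfile:
    """Per-channel ΔE from a windowed entropy matrix and clinical markers.

    Non-finite window values are excluded from the baseline mean and ictal
    minimum; a channel with no finite value in either period is flagged
    non-finite (NaN) with a warning and should be excluded downstream.
    """
    segs = segment_windows(matrix, timeline, params, exclude_labels)
    base = matrix.values[:, segs["baseline"]]
    ictal = matrix.values[:, segs["ictal"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        baseline_mean = np.nanmean(base, axis=1)
        ictal_min = np.nanmin(ictal, axis=1)
    bad = ~np.isfinite(baseline_mean) | ~np.isfinite(ictal_min)
    if bad.any():
        names = [matrix.channel_labels[i] if matrix.channel_labels else str(i)
                 for i in np.flatnonzero(bad)]
        warnings.warn(
            f"channels with no finite baseline/ictal PE flagged non-finite: {names}",
            stacklevel=2,
        )
    return DeltaEntropyProfile(
        channel_labels=matrix.channel_labels or [str(i) for i in range(matrix.n_channels)],
        baseline_mean=baseline_mean,
        ictal_min=ictal_min,
        n_baseline_windows=int(segs["baseline"].size),
        n_ictal_windows=int(segs["ictal"].size),
        sign=sign,
    )
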