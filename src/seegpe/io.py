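"""Recordings, event timelines, and the adjacent-contact bipolar montage.

All seizure analyses run on nonartifacted depth-electrode channels
re-referenced to a bipolar montage: each channel is the difference of two
adjacent contacts on the same electrode shaft (B1-B2, B2-B3, ...).  Artifacted
contacts are excluded by an explicit, user-supplied list — exclusion criteria
are a curation decision, not something this package infers from the signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edf import probe_header

__all__ = [
    "Recording",
    "Event",
    "EventTimeline",
    "BipolarMontage",
    "read_recording",
    "parse_markers",
    "build_bipolar_montage",
    "apply_montage",
]

#: contact labels are one-or-more letters (primes allowed, e.g. B') + a 1-based index
_CONTACT_RE = re.compile(r"^([A-Za-z']+?)(\d+)$")

#: canonical marker labels; unknown labels pass through untouched
UNIQUE_MARKERS = ("baseline_end", "seizure_onset", "seizure_offset")


@dataclass
class Recording:
    """Multichannel signal block (channels x time, physical µV)."""

    samples: np.ndarray
    sampling_rate_hz: float
    labels: list[str]
    montage_kind: str = "referential"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.montage_kind not in ("referential", "bipolar"):
            raise ValueError(f"unknown montage_kind {self.montage_kind!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz


@dataclass(frozen=True)
class Event:
    label: str
    onset_s: float
    duration_s: float = 0.0


@dataclass
class EventTimeline:
    """Labeled clinical time points/intervals, kept sorted by onset."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.onset_s < 0:
                raise ValueError(f"event {ev.label!r} has negative onset {ev.onset_s}")
            if ev.duration_s < 0:
                raise ValueError(f"event {ev.label!r} has negative duration {ev.duration_s}")
        for lab in UNIQUE_MARKERS:
            if sum(ev.label == lab for ev in self.events) > 1:
                raise ValueError(f"marker {lab!r} must occur at most once")
        self.events = sorted(self.events, key=lambda ev: ev.onset_s)

    def onset_of(self, label: str) -> float:
        """Onset of a uniquely labeled marker; KeyError if absent."""
        for ev in self.events:
            if ev.label == label:
                return ev.onset_s
        raise KeyError(f"marker {label!r} not found in timeline")

    def with_label(self, label_prefix: str) -> list[Event]:
        return [ev for ev in self.events if ev.label.startswith(label_prefix)]


def read_recording(path) -> Recording:
    """Read an EDF/EDF+ recording via MNE; annotation channels are dropped.

    All signal channels must share one sampling rate; values are returned in
    physical µV.
    """
    info = probe_header(path)
    signal_idx = [i for i, lab in enumerate(info.labels) if "EDF Annotations" not in lab]
    if not signal_idx:
        raise IOError(f"no signal channels in {path}")
    rates = {info.rates_hz[i] for i in signal_idx}
    if len(rates) > 1:
        raise ValueError(
            f"unsupported EDF: mixed sampling rates {sorted(rates)} across signal channels in {path}"
        )
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # mne raises a mix of ValueError/OSError subtypes
        raise IOError(f"cannot read EDF file {path}: {err}") from err
    data = raw.get_data(units="uV")
    return Recording(
        samples=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        montage_kind="referential",
    )


def parse_markers(path) -> EventTimeline:
    """Parse a tab-separated marker file (columns: label, onset_s, duration_s).

    An empty duration field is treated as 0; events are returned sorted by
    onset and unknown labels are preserved verbatim.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "onset_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "duration_s" not in df.columns:
        df["duration_s"] = 0.0
    df["duration_s"] = df["duration_s"].fillna(0.0)
    if (df["onset_s"] < 0).any():
        bad = df.loc[df["onset_s"] < 0, "label"].iloc[0]
        raise ValueError(f"{path}: negative onset for event {bad!r}")
    events = [
        Event(str(r.label), float(r.onset_s), float(r.duration_s)) for r in df.itertuples()
    ]
    return EventTimeline(events=events)


@dataclass
class BipolarMontage:
    """Ordered adjacent-contact pairs, one per derived bipolar channel."""

    pairs: list[tuple[str, str]]

    def pair_labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]


def _parse_contact(label: str) -> tuple[str, int]:
    m = _CONTACT_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse contact label {label!r} (expected e.g. B3, H'12)")
    return m.group(1), int(m.group(2))


def build_bipolar_montage(labels, exclude=()) -> BipolarMontage:
    """Pairs of adjacent same-electrode contacts, skipping excluded ones.

    For each electrode prefix, contacts with consecutive indices i, i+1 form a
    pair; a gap in the index sequence never pairs.  ``exclude`` may list
    contact labels or derived pair names ("B1-B2").  Order: electrode prefixes
    alphabetically, indices ascending.
    """
    excluded = {e.strip() for e in exclude}
    by_electrode: dict[str, dict[int, str]] = {}
    for lab in labels:
        prefix, idx = _parse_contact(lab)
        by_electrode.setdefault(prefix, {})[idx] = lab.strip()
    pairs = []
    for prefix in sorted(by_electrode):
        contacts = by_electrode[prefix]
        for idx in sorted(contacts):
            if idx + 1 not in contacts:
                continue
            a, c = contacts[idx], contacts[idx + 1]
            if a in excluded or c in excluded or f"{a}-{c}" in excluded:
                continue
            pairs.append((a, c))
    return BipolarMontage(pairs=pairs)


def apply_montage(recording: Recording, montage: BipolarMontage) -> Recording:
    """Re-reference a referential recording: bipolar channel = anode - cathode."""
    if recording.montage_kind != "referential":
        raise ValueError("apply_montage expects a referential recording")
    index = {lab: i for i, lab in enumerate(recording.labels)}
    missing = [lab for pair in montage.pairs for lab in pair if lab not in index]
    if missing:
        raise ValueError(f"montage contacts missing from recording: {sorted(set(missing))}")
    rows = [
        recording.samples[index[a]] - recording.samples[index[c]] for a, c in montage.pairs
    ]
    return Recording(
        samples=np.array(rows) if rows else np.empty((0, recording.samples.shape[1])),
        sampling_rate_hz=recording.sampling_rate_hz,
        labels=montage.pair_labels(),
        montage_kind="bipolar",
    )
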