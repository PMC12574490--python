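"""Synthetic SEEG seizure generator with known complexity structure.

No clinical recordings ship with this package, so every downstream stage is
exercised on simulated bipolar SEEG with an imposed, measurable entropy
structure:

* baseline — pink (1/f) noise per channel: high ordinal complexity (PE ~0.99
  at 256 Hz, D=3), physiological broadband spectrum;
* inducing-stimulation epoch — background noise continues (markers only);
* ictal discharge — quasi-periodic rhythm (dominant sinusoid at
  ``ictal_freq_hz`` plus a second harmonic at half amplitude) blended with
  pink noise by ``ictal_noise_fraction``: low ordinal complexity, tunable;
* optional pulvinar pulses — intervals of the ictal segment blended with
  fresh broadband noise by ``pulse_restoration``, transiently restoring
  complexity;
* postictal tail — background noise again.

Because permutation entropy is amplitude-invariant, all complexity control
happens through ordinal structure (noise blending), never amplitude.  The
generator draws every random stream unconditionally in a fixed order, so the
same seed yields bit-identical non-pulse samples across different
``ictal_noise_fraction`` / ``pulse_restoration`` settings.

The module also packages the study's clinical-parameters table (stimulation
settings, electrographic durations, and Consciousness Seizure Scale scores
for the 11 matched seizure pairs) and writes EDF/marker files for round-trip
testing of the readers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf as _edf
from .entropy import PEParams, permutation_entropy
from .io import Event, EventTimeline, Recording

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_seizure_recording",
    "noise_fraction_for_drop",
    "make_table1_fixture",
    "write_edf",
    "write_markers",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one simulated seizure; identical params + seed => bit-identical output."""

    n_channels: int = 12
    sampling_rate_hz: float = 256.0
    baseline_dur_s: float = 20.0
    stim_dur_s: float = 10.0
    ictal_dur_s: float = 40.0
    postictal_dur_s: float = 10.0
    ictal_freq_hz: float = 7.0
    ictal_noise_fraction: float = 0.1
    pulvinar_pulses: tuple[tuple[float, float], ...] = ()
    pulse_restoration: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        for name in ("baseline_dur_s", "stim_dur_s", "ictal_dur_s", "postictal_dur_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.total_dur_s <= 0:
            raise ValueError("total duration must be positive")
        for name in ("ictal_noise_fraction", "pulse_restoration"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ictal_freq_hz <= 0:
            raise ValueError(f"ictal_freq_hz must be positive, got {self.ictal_freq_hz}")

    @property
    def total_dur_s(self) -> float:
        return self.baseline_dur_s + self.stim_dur_s + self.ictal_dur_s + self.postictal_dur_s


@dataclass
class GroundTruth:
    """Realized complexity structure of one simulated seizure.

    ``drop`` is the imposed entropy-drop magnitude per channel: whole-segment
    baseline PE minus whole-segment ictal PE (pulse intervals excluded),
    computed on the generated samples at D=3, tau=1.
    """

    channel_labels: list[str]
    baseline_pe: np.ndarray
    ictal_pe: np.ndarray
    drop: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.baseline_pe = np.asarray(self.baseline_pe, dtype=float)
        self.ictal_pe = np.asarray(self.ictal_pe, dtype=float)
        if not (len(self.channel_labels) == self.baseline_pe.size == self.ictal_pe.size):
            raise ValueError("one ground-truth entry per channel required")
        self.drop = self.baseline_pe - self.ictal_pe

    def band(self, segment: str, margin: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Expected (low, high) PE band per channel for 'baseline' or 'ictal'."""
        pe = {"baseline": self.baseline_pe, "ictal": self.ictal_pe}[segment]
        return np.maximum(pe - margin, 0.0), np.minimum(pe + margin, 1.0)


def _pink_noise(rng: np.random.Generator, n: int, rate_hz: float) -> np.ndarray:
    """Unit-variance 1/f ('pink') noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate_hz)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _default_pair_labels(n: int) -> list[str]:
    """Bipolar-style channel names: B1-B2 ... B4-B5, C1-C2, ... across electrodes."""
    letters = "BCDHJKLMNOPQRSTUVWXYZ"
    labels, per_electrode = [], 4
    for k in range(n):
        e, i = divmod(k, per_electrode)
        prefix = letters[e % len(letters)] + "'" * (e // len(letters))
        labels.append(f"{prefix}{i + 1}-{prefix}{i + 2}")
    return labels


def simulate_seizure_recording(
    params: SimulationParams,
) -> tuple[Recording, EventTimeline, GroundTruth]:
    """Generate one seizure: bipolar recording, event timeline, ground truth.

    Timeline markers: ``baseline_end`` (disconnection of the stimulated
    contacts, which here coincides with stimulation start), ``stim_on``,
    ``seizure_onset``, ``pulvinar_pulse_k`` (one per pulse, with duration),
    ``seizure_offset``.
    """
    rate = params.sampling_rate_hz
    n_total = int(round(params.total_dur_s * rate))
    i_stim = int(round(params.baseline_dur_s * rate))
    i_onset = int(round((params.baseline_dur_s + params.stim_dur_s) * rate))
    i_offset = int(round((params.baseline_dur_s + params.stim_dur_s + params.ictal_dur_s) * rate))
    onset_s = i_onset / rate

    rng = np.random.default_rng(params.seed)
    # pulses draw from an independent stream so adding/removing them (or
    # changing restoration) leaves the background samples bit-identical
    pulse_rng = np.random.default_rng([params.seed, 0x9E37])
    t_ictal = np.arange(i_offset - i_onset) / rate
    pulse_spans = []
    for rel_on, dur in params.pulvinar_pulses:
        if dur < 0:
            raise ValueError(f"pulvinar pulse duration must be >= 0, got {dur}")
        a = i_onset + int(round(rel_on * rate))
        b = a + int(round(dur * rate))
        pulse_spans.append((max(a, i_onset), min(b, i_offset)))

    data = np.empty((params.n_channels, n_total))
    base_pe = np.empty(params.n_channels)
    ict_pe = np.empty(params.n_channels)
    ictal_mask = np.zeros(n_total, dtype=bool)
    ictal_mask[i_onset:i_offset] = True
    nonpulse_mask = ictal_mask.copy()
    for a, b in pulse_spans:
        nonpulse_mask[a:b] = False

    pe_params = PEParams(D=3, tau=1)
    for ch in range(params.n_channels):
        # fixed draw order => streams identical across noise/restoration settings
        background = _pink_noise(rng, n_total, rate)
        phase = rng.uniform(0, 2 * math.pi)
        pulse_noises = [_pink_noise(pulse_rng, max(b - a, 1), rate) for a, b in pulse_spans]

        x = background.copy()
        if i_offset > i_onset:
            rhythm = np.sin(2 * math.pi * params.ictal_freq_hz * t_ictal + phase)
            rhythm += 0.5 * np.sin(2 * math.pi * 2 * params.ictal_freq_hz * t_ictal + 2 * phase)
            rhythm /= max(rhythm.std(), 1e-12)
            frac = params.ictal_noise_fraction
            x[i_onset:i_offset] = 3.0 * (
                (1 - frac) * rhythm + frac * background[i_onset:i_offset]
            )
            for (a, b), noise in zip(pulse_spans, pulse_noises):
                if b > a and params.pulse_restoration > 0:
                    r = params.pulse_restoration
                    x[a:b] = (1 - r) * x[a:b] + 3.0 * r * noise[: b - a]
        data[ch] = 30.0 * x  # physiological-ish µV scale; PE is amplitude-invariant

        base_pe[ch] = (
            permutation_entropy(x[:i_stim], pe_params) if i_stim >= pe_params.span else np.nan
        )
        ict = x[nonpulse_mask] if nonpulse_mask.sum() >= pe_params.span else x[ictal_mask]
        ict_pe[ch] = permutation_entropy(ict, pe_params) if ict.size >= pe_params.span else np.nan

    labels = _default_pair_labels(params.n_channels)
    events = [
        Event("baseline_end", params.baseline_dur_s),
        Event("stim_on", params.baseline_dur_s, params.stim_dur_s),
        Event("seizure_onset", onset_s),
    ]
    for k, (rel_on, dur) in enumerate(params.pulvinar_pulses, start=1):
        events.append(Event(f"pulvinar_pulse_{k}", onset_s + rel_on, dur))
    events.append(Event("seizure_offset", i_offset / rate))

    recording = Recording(
        samples=data, sampling_rate_hz=rate, labels=labels, montage_kind="bipolar"
    )
    truth = GroundTruth(channel_labels=labels, baseline_pe=base_pe, ictal_pe=ict_pe)
    return recording, EventTimeline(events=events), truth


def noise_fraction_for_drop(
    target_drop: float,
    params: SimulationParams,
    tol: float = 0.005,
    max_iter: int = 30,
) -> float:
    """Invert the noise-fraction -> entropy-drop map by bisection.

    Runs the generator itself on a single-channel prototype with the given
    seed and segment durations and bisects ``ictal_noise_fraction`` until the
    realized mean drop matches ``target_drop``.  The map is monotone
    (more broadband noise => higher ictal PE => smaller drop).
    """
    proto = replace(params, n_channels=1, pulvinar_pulses=(), pulse_restoration=0.0)

    def drop_at(frac: float) -> float:
        _, _, truth = simulate_seizure_recording(replace(proto, ictal_noise_fraction=frac))
        return float(truth.drop.mean())

    lo, hi = 0.0, 1.0  # drop(0) is max, drop(1) ~ 0
    d_lo = drop_at(lo)
    if target_drop >= d_lo:
        return lo
    if target_drop <= 0:
        return hi
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        d = drop_at(mid)
        if abs(d - target_drop) < tol:
            return mid
        if d > target_drop:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# --- clinical-parameters fixture -------------------------------------------------
# One row per seizure of the 11 matched pairs (22 rows, 19 distinct seizures).
# Reused seizures ("bis" pairs re-compare a seizure already used for that
# patient) carry the seizure_id of the original row: the P4bis/P7bis PUM+ rows
# are cell-identical to P4/P7 PUM+, while for P5bis it is the PUM- row that is
# cell-identical to P5 PUM- (the P5bis PUM+ seizure differs in duration).
# Pulvinar fields are None for PUM- seizures (no pulvinar stimulation).
_TABLE1_ROWS = [
    # pair,  patient, cond,  hipf, hipw, hipa, hipd,  pumf, pumw, puma, pumd,  eeg, css, seizure_id
    ("P1", "P1", "PUM+", 50, 1000, 1.8, 5.0, 130, 450, 1.0, 5.55, 100.0, 5, "P1_plus"),
    ("P1", "P1", "PUM-", 50, 1000, 1.8, 5.0, None, None, None, None, 65.0, 4, "P1_minus"),
    ("P2", "P2", "PUM+", 1, 2000, 2.0, 15.6, 130, 450, 1.0, 5.41, 36.0, 0, "P2_plus"),
    ("P2", "P2", "PUM-", 1, 2000, 2.0, 14.1, None, None, None, None, 50.0, 0, "P2_minus"),
    ("P3", "P3", "PUM+", 50, 1000, 1.5, 4.0, 130, 450, 1.0, 3.16, 65.0, 1, "P3_plus"),
    ("P3", "P3", "PUM-", 50, 1000, 1.5, 4.0, None, None, None, None, 67.0, 4, "P3_minus"),
    ("P4", "P4", "PUM+", 1, 2000, 1.0, 19.0, 130, 450, 2.0, 7.7, 32.0, 0, "P4_plus"),
    ("P4", "P4", "PUM-", 1, 2000, 1.0, 19.0, None, None, None, None, 25.0, 0, "P4_minus"),
    ("P4bis", "P4", "PUM+", 1, 2000, 1.0, 19.0, 130, 450, 2.0, 7.7, 32.0, 0, "P4_plus"),
    ("P4bis", "P4", "PUM-", 1, 2000, 2.0, 21.2, None, None, None, None, 113.0, 9, "P4bis_minus"),
    ("P5", "P5", "PUM+", 1, 2000, 1.0, 60.0, 130, 450, 2.0, 6.94, 52.0, 0, "P5_plus"),
    ("P5", "P5", "PUM-", 1, 2000, 1.0, 11.4, None, None, None, None, 33.0, 3, "P5_minus"),
    ("P5bis", "P5", "PUM+", 1, 2000, 1.0, 60.0, 130, 450, 2.0, 6.94, 54.0, 0, "P5bis_plus"),
    ("P5bis", "P5", "PUM-", 1, 2000, 1.0, 11.4, None, None, None, None, 33.0, 3, "P5_minus"),
    ("P6", "P6", "PUM+", 1, 2000, 1.5, 15.1, 130, 450, 2.0, 5.54, 74.0, 8, "P6_plus"),
    ("P6", "P6", "PUM-", 1, 2000, 1.5, 13.3, None, None, None, None, 92.0, 9, "P6_minus"),
    ("P7", "P7", "PUM+", 50, 1000, 1.2, 5.0, 130, 450, 1.0, 5.56, 35.0, 0, "P7_plus"),
    ("P7", "P7", "PUM-", 50, 1000, 0.8, 5.0, None, None, None, None, 32.0, 0, "P7_minus"),
    ("P7bis", "P7", "PUM+", 50, 1000, 1.2, 5.0, 130, 450, 1.0, 5.56, 35.0, 0, "P7_plus"),
    ("P7bis", "P7", "PUM-", 1, 2000, 1.0, 13.1, None, None, None, None, 27.0, 0, "P7bis_minus"),
    ("P8", "P8", "PUM+", 1, 2000, 1.0, 14.2, 130, 450, 1.0, 5.41, 151.0, 4, "P8_plus"),
    ("P8", "P8", "PUM-", 1, 2000, 2.5, 6.1, None, None, None, None, 138.0, 4, "P8_minus"),
]

_TABLE1_COLUMNS = [
    "pair_label",
    "patient_label",
    "condition",
    "hip_freq_hz",
    "hip_pulse_us",
    "hip_amp_ma",
    "hip_dur_s",
    "pum_freq_hz",
    "pum_pulse_us",
    "pum_amp_ma",
    "pum_dur_s",
    "eeg_dur_s",
    "css",
    "seizure_id",
]


def make_table1_fixture() -> pd.DataFrame:
    """The study's clinical-parameters table: 22 rows, 11 matched pairs.

    Each row is one seizure of a PUM+/PUM- pair with its hippocampal
    induction parameters, pulvinar stimulation parameters (PUM+ only),
    electrographic seizure duration, and CSS score.  ``seizure_id``
    identifies the physically distinct seizure (19 distinct across 22 rows).
    """
    df = pd.DataFrame(_TABLE1_ROWS, columns=_TABLE1_COLUMNS)
    return df.astype({"hip_freq_hz": int, "hip_pulse_us": int, "css": int})


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as 16-bit EDF (see the edf module for the layout)."""
    _edf.write_edf(recording.samples, recording.sampling_rate_hz, recording.labels, path)


def write_markers(timeline: EventTimeline, path) -> None:
    """Write the event timeline as the tab-separated marker format."""
    df = pd.DataFrame(
        [(ev.label, ev.onset_s, ev.duration_s) for ev in timeline.events],
        columns=["label", "onset_s", "duration_s"],
    )
    df.to_csv(path, sep="\t", index=False)


# --- full synthetic study --------------------------------------------------------

def _study_durations(hip_dur_s: float, eeg_dur_s: float, scale: float) -> dict:
    """Segment durations for one study seizure, optionally scaled down."""
    return dict(
        baseline_dur_s=15.0,
        stim_dur_s=max(2.5, hip_dur_s * scale),
        ictal_dur_s=max(15.0, eeg_dur_s * scale),
        postictal_dur_s=5.0,
    )


def simulate_study(
    out_dir,
    seed: int = 0,
    n_channels: int = 8,
    n_pairs: int | None = None,
    base_drop: float = 0.25,
    css_gain: float = 0.03,
    drop_jitter_sd: float = 0.0,
    duration_scale: float = 1.0,
    pulse_restoration: float = 0.5,
) -> Path:
    """Generate a full synthetic study directory mirroring the clinical table.

    One EDF + marker file per distinct seizure, the clinical-parameters
    fixture, and a JSON manifest listing the PUM-/PUM+ pairing.  The imposed
    entropy drop of each seizure grows in proportion to its CSS score
    (``base_drop + css_gain * css``), encoding the studied coupling between
    complexity loss and awareness impairment; ``drop_jitter_sd`` optionally
    adds Gaussian per-seizure scatter around that proportionality for
    sensitivity analyses.  PUM+ seizures additionally receive pulvinar pulses
    that transiently restore complexity.
    """
    out = Path(out_dir)
    (out / "seizures").mkdir(parents=True, exist_ok=True)
    fixture = make_table1_fixture()
    if n_pairs is not None:
        keep = list(dict.fromkeys(fixture["pair_label"]))[:n_pairs]
        fixture = fixture[fixture["pair_label"].isin(keep)].reset_index(drop=True)
    fixture.to_csv(out / "fixture.csv", index=False)

    rng = np.random.default_rng(seed)
    distinct = fixture.drop_duplicates("seizure_id")
    files: dict[str, dict] = {}
    for _, row in distinct.iterrows():
        sid = row["seizure_id"]
        durs = _study_durations(float(row["hip_dur_s"]), float(row["eeg_dur_s"]), duration_scale)
        target = float(
            np.clip(base_drop + css_gain * row["css"] + rng.normal(0, drop_jitter_sd), 0.05, 0.5)
        )
        sim_seed = int(rng.integers(0, 2**31 - 1))
        pulses: tuple[tuple[float, float], ...] = ()
        if row["condition"] == "PUM+":
            # pulses are transient: the first half of the ictal period stays
            # pulse-free so the windowed ictal minimum reflects the imposed drop
            pdur = min(float(row["pum_dur_s"]) * duration_scale, 0.2 * durs["ictal_dur_s"])
            first = 0.5 * durs["ictal_dur_s"]
            second = first + pdur + 3.0
            pulses = ((first, pdur),)
            if second + pdur <= durs["ictal_dur_s"]:
                pulses += ((second, pdur),)
        params = SimulationParams(
            n_channels=n_channels,
            seed=sim_seed,
            pulvinar_pulses=pulses,
            pulse_restoration=pulse_restoration if pulses else 0.0,
            **durs,
        )
        frac = noise_fraction_for_drop(target, params)
        rec, timeline, truth = simulate_seizure_recording(
            replace(params, ictal_noise_fraction=frac)
        )
        edf_path = out / "seizures" / f"{sid}.edf"
        mrk_path = out / "seizures" / f"{sid}.markers.tsv"
        write_edf(rec, edf_path)
        write_markers(timeline, mrk_path)
        files[sid] = {
            "edf": str(edf_path.relative_to(out)),
            "markers": str(mrk_path.relative_to(out)),
            "target_drop": target,
            "noise_fraction": frac,
            "mean_true_drop": float(np.nanmean(truth.drop)),
        }

    pairs = []
    for pair, grp in fixture.groupby("pair_label", sort=False):
        by_cond = dict(zip(grp["condition"], grp["seizure_id"]))
        pairs.append({"pair_label": pair, "minus": by_cond["PUM-"], "plus": by_cond["PUM+"]})
    manifest = {
        "seed": seed,
        "n_channels": n_channels,
        "sampling_rate_hz": 256.0,
        "seizures": files,
        "pairs": pairs,
        "fixture": "fixture.csv",
    }
    with open(out / "study.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
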