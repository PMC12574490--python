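"""Figure rendering and the end-to-end study pipeline.

Outputs mirror the standard presentation of windowed-complexity seizure
analyses: per-seizure channel x window entropy heatmaps with vertical event
bars, the global (channel-mean) complexity curve, and per-pair ΔE boxplots.
``run_pipeline`` ties the stages together over a study directory produced by
the simulator (or assembled by hand in the same layout) and writes every
intermediate as CSV/JSON so any stage can be re-run or audited in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .delta import DeltaEntropyProfile, SegmentationParams, compute_delta_entropy
from .entropy import (
    EntropyMatrix,
    PEParams,
    WindowingParams,
    global_entropy_curve,
    sliding_window_pe,
)
from .io import EventTimeline, apply_montage, build_bipolar_montage, parse_markers, read_recording
from .stats import bonferroni, classify_css_changes, compare_pair, correlate_css_deltaE, summarize_stim_params

log = logging.getLogger("seegpe")

__all__ = ["RunConfig", "render_heatmap", "render_global_curve", "run_pipeline"]


def _event_bars(ax, timeline: EventTimeline, t_max: float) -> None:
    for k, ev in enumerate(timeline.events, start=1):
        t = min(max(ev.onset_s, 0.0), t_max)  # clip off-axis markers
        ax.axvline(t, color="white" if ax.images else "k", lw=1.0, ls="--", alpha=0.8)
        ax.annotate(str(k), (t, 1.0), xycoords=("data", "axes fraction"),
                    ha="center", va="bottom", fontsize=7)


def render_heatmap(matrix: EntropyMatrix, timeline: EventTimeline, path) -> None:
    """Channels x windows PE raster, color scale fixed to [0, 1] (viridis:
    dark blue = organized/low entropy, bright yellow = chaotic/high entropy),
    with vertical bars at event onsets."""
    if matrix.n_channels == 0 or matrix.n_windows == 0:
        raise ValueError("cannot render an empty entropy matrix")
    fig, ax = plt.subplots(figsize=(8, 0.25 * matrix.n_channels + 2))
    t = matrix.window_centers_s
    ax.imshow(
        matrix.values,
        aspect="auto",
        origin="upper",
        cmap="viridis",
        vmin=0.0,
        vmax=1.0,
        extent=[t[0], t[-1], matrix.n_channels - 0.5, -0.5],
        interpolation="nearest",
    )
    _event_bars(ax, timeline, t[-1])
    if matrix.channel_labels and matrix.n_channels <= 32:
        ax.set_yticks(range(matrix.n_channels), matrix.channel_labels, fontsize=6)
    ax.set_xlabel("time (s)")
    ax.set_title("permutation entropy")
    fig.colorbar(ax.images[0], ax=ax, label="PE")
    _save(fig, path)


def render_global_curve(curve, timeline: EventTimeline, centers_s, path) -> None:
    """Global complexity trend (channel-mean PE per window) with numbered event bars."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("cannot render an empty curve")
    centers = np.asarray(centers_s, dtype=float)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(centers, curve, color="tab:blue")
    ax.set_ylim(0, 1.02)
    _event_bars(ax, timeline, centers[-1])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean PE")
    _save(fig, path)


def render_pair_boxplots(profiles: dict[str, tuple[DeltaEntropyProfile, DeltaEntropyProfile]],
                         css: dict[str, tuple[int, int]], path) -> None:
    """Per-pair ΔE boxplots: PUM- (green) vs PUM+ (red), one dot per bipolar channel."""
    if not profiles:
        raise ValueError("no pairs to plot")
    fig, ax = plt.subplots(figsize=(1.2 * len(profiles) + 2, 4))
    pos = 0
    ticks, ticklabels = [], []
    for pair, (pm, pp) in profiles.items():
        for prof, color, dx in ((pm, "tab:green", 0), (pp, "tab:red", 1)):
            vals = prof.delta_e[np.isfinite(prof.delta_e)]
            bp = ax.boxplot(vals, positions=[pos + dx], widths=0.6, patch_artist=True,
                            showfliers=False)
            bp["boxes"][0].set_facecolor(color)
            ax.plot(np.full(vals.size, pos + dx) + np.linspace(-0.15, 0.15, vals.size),
                    vals, ".", color="k", ms=3, alpha=0.6)
        ticks.append(pos + 0.5)
        c = css.get(pair, ("", ""))
        ticklabels.append(f"{pair}\nCSS {c[1]}/{c[0]}")
        pos += 3
    ax.set_xticks(ticks, ticklabels, fontsize=7)
    ax.set_ylabel("ΔE (baseline − ictal min)")
    _save(fig, path)


def _save(fig, path) -> None:
    try:
        fig.savefig(path, dpi=110)
    except OSError as err:
        raise IOError(f"cannot write figure {path}: {err}") from err
    finally:
        plt.close(fig)


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run depends on."""

    study_dir: str
    out_dir: str
    pe: PEParams = field(default_factory=PEParams)
    win: WindowingParams = field(default_factory=WindowingParams)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    exclude: tuple[str, ...] = ()
    delta_sign: str = "drop"
    pair_stat: str = "median"
    bonferroni_m: int | None = None
    figures: bool = True
    reuse_entropy: bool = False
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = dict(raw)
        if "pe" in kwargs:
            kwargs["pe"] = PEParams(**kwargs["pe"])
        if "win" in kwargs:
            kwargs["win"] = WindowingParams(**kwargs["win"])
        if "seg" in kwargs:
            kwargs["seg"] = SegmentationParams(**kwargs["seg"])
        if "exclude" in kwargs:
            kwargs["exclude"] = tuple(kwargs["exclude"])
        return cls(**kwargs)


def _stage(name: str):
    """Wrap a pipeline stage so failures abort with the stage name and context."""

    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis over a study directory; returns the results dir.

    Per seizure: entropy CSV, ΔE CSV, figures.  Per pair: Wilcoxon comparison
    row (Bonferroni-adjusted).  Study level: CSS-change classification,
    CSS-ΔE Spearman correlation JSON, stimulation-parameter summaries, and a
    machine-readable manifest of all parameters for bit-identical re-runs.
    """
    study = Path(config.study_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(study / "study.json") as fh:
        manifest = json.load(fh)
    fixture = pd.read_csv(study / manifest.get("fixture", "fixture.csv"))

    profiles: dict[str, DeltaEntropyProfile] = {}
    timelines: dict[str, EventTimeline] = {}
    for sid, paths in manifest["seizures"].items():
        timeline = _stage("markers")(parse_markers, study / paths["markers"])
        timelines[sid] = timeline
        entropy_csv = out / f"{sid}.entropy.csv"
        if config.reuse_entropy and entropy_csv.exists():
            matrix = _stage("entropy-load")(EntropyMatrix.from_csv, entropy_csv)
            log.info("seizure %s: reused %s (%d channels, %d windows)",
                     sid, entropy_csv.name, matrix.n_channels, matrix.n_windows)
        else:
            rec = _stage("read")(read_recording, study / paths["edf"])
            if rec.montage_kind == "referential" and not _looks_bipolar(rec.labels):
                montage = _stage("montage")(build_bipolar_montage, rec.labels, config.exclude)
                rec = _stage("montage")(apply_montage, rec, montage)
            elif config.exclude:
                keep = [i for i, lab in enumerate(rec.labels) if lab not in config.exclude]
                log.info("seizure %s: excluding %d channels", sid, rec.n_channels - len(keep))
                rec = dataclasses.replace(
                    rec, samples=rec.samples[keep], labels=[rec.labels[i] for i in keep]
                )
            matrix = _stage("entropy")(sliding_window_pe, rec, config.pe, config.win)
            matrix.to_csv(entropy_csv)
            log.info("seizure %s: %d channels x %d windows", sid, matrix.n_channels,
                     matrix.n_windows)
        profile = _stage("segmentation")(
            compute_delta_entropy, matrix, timeline, config.seg, config.delta_sign
        )
        profile.to_csv(out / f"{sid}.delta_e.csv")
        profiles[sid] = profile
        if config.figures:
            _stage("figures")(render_heatmap, matrix, timeline, out / f"{sid}.heatmap.png")
            curve = global_entropy_curve(matrix)
            _stage("figures")(
                render_global_curve, curve, timeline, matrix.window_centers_s,
                out / f"{sid}.global_pe.png",
            )

    comparisons = []
    pair_profiles = {}
    for pair in manifest["pairs"]:
        cmp_ = _stage("pair-comparison")(
            compare_pair, profiles[pair["minus"]], profiles[pair["plus"]],
            pair["pair_label"], config.pair_stat,
        )
        comparisons.append(cmp_)
        pair_profiles[pair["pair_label"]] = (profiles[pair["minus"]], profiles[pair["plus"]])
    adjusted = bonferroni([c.p_raw for c in comparisons], config.bonferroni_m)
    for c, p_adj in zip(comparisons, adjusted):
        c.p_adjusted = p_adj
    cmp_df = pd.DataFrame([dataclasses.asdict(c) for c in comparisons])
    cmp_df.to_csv(out / "pair_comparisons.csv", index=False)

    counts, per_pair = _stage("css")(classify_css_changes, fixture)
    per_pair.to_csv(out / "css_changes.csv", index=False)
    ddE = {
        c.pair_label: c.delta_e_summary_plus - c.delta_e_summary_minus for c in comparisons
    }
    merged = per_pair[per_pair["pair_label"].isin(ddE)]
    try:
        corr = correlate_css_deltaE(
            merged["delta_css"].tolist(), [ddE[p] for p in merged["pair_label"]]
        )
        corr_payload = {"rho": corr.rho, "p_value": corr.p_value, "n_pairs": corr.n_pairs}
    except ValueError as err:  # undefined (< 3 pairs or zero variance): report, don't abort
        log.warning("correlation undefined: %s", err)
        corr_payload = {"rho": None, "p_value": None, "n_pairs": int(len(merged)),
                        "undefined_reason": str(err)}
    with open(out / "correlation.json", "w") as fh:
        json.dump(
            {**corr_payload, "css_change_counts": counts, "delta_e_sign": config.delta_sign},
            fh, indent=2,
        )

    summaries = []
    for group in ("1 Hz", "50 Hz", "PUM"):
        try:
            s = summarize_stim_params(fixture, group)
        except ValueError:
            continue
        s.insert(0, "group", group)
        summaries.append(s)
    if summaries:
        pd.concat(summaries).to_csv(out / "stim_param_summaries.csv", index=False)

    if config.figures:
        css_by_pair = {
            r["pair_label"]: 0 for _, r in per_pair.iterrows()
        }
        css_lookup = {}
        for pair, grp in fixture.groupby("pair_label", sort=False):
            by_cond = dict(zip(grp["condition"], grp["css"]))
            css_lookup[pair] = (by_cond.get("PUM-", ""), by_cond.get("PUM+", ""))
        _stage("figures")(render_pair_boxplots, pair_profiles, css_lookup,
                          out / "pair_boxplots.png")

    run_manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "pe": dataclasses.asdict(config.pe),
            "win": dataclasses.asdict(config.win),
            "seg": dataclasses.asdict(config.seg),
            "exclude": list(config.exclude),
            "delta_sign": config.delta_sign,
            "pair_stat": config.pair_stat,
            "bonferroni_m": config.bonferroni_m,
        },
        "study": str(study),
        "n_seizures": len(profiles),
        "n_pairs": len(comparisons),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    return out


def _looks_bipolar(labels) -> bool:
    return all("-" in lab for lab in labels)
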