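"""Paired statistics over matched PUM-/PUM+ seizures and clinical summaries.

Per matched pair (same patient, same hippocampal induction contacts, same
montage), the per-channel ΔE values of the two conditions are compared with a
paired two-sided Wilcoxon signed-rank test; p-values are Bonferroni-corrected
across the pairs of a run.  Awareness changes are classified from CSS scores
(delta_css = CSS(PUM+) - CSS(PUM-); improvement = negative delta, the scale
grows with impairment), and the coupling between awareness change and
complexity change is measured by Spearman rank correlation of per-pair
delta_css against per-pair ΔΔE (one ΔE scalar per seizure, median across
channels by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .delta import DeltaEntropyProfile

__all__ = [
    "PairComparison",
    "CorrelationResult",
    "compare_pair",
    "bonferroni",
    "classify_css_changes",
    "correlate_css_deltaE",
    "summarize_stim_params",
]

#: switch from the exact signed-rank null to the continuity-corrected normal
#: approximation above this many nonzero differences
_EXACT_LIMIT = 25


@dataclass
class PairComparison:
    pair_label: str
    n_channels: int
    wilcoxon_statistic: float
    p_raw: float
    p_adjusted: float | None
    delta_e_summary_minus: float
    delta_e_summary_plus: float
    sign: str


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int


def compare_pair(
    profile_minus: DeltaEntropyProfile,
    profile_plus: DeltaEntropyProfile,
    pair_label: str = "",
    summary: str = "median",
) -> PairComparison:
    """Paired Wilcoxon signed-rank test over per-channel ΔE of one seizure pair.

    Channels must match exactly (seizures of one patient share a montage).
    Zero differences are dropped (Wilcoxon's original convention); the exact
    null distribution is used up to 25 nonzero differences, the normal
    approximation with continuity correction beyond.
    """
    if profile_minus.channel_labels != profile_plus.channel_labels:
        only_minus = set(profile_minus.channel_labels) - set(profile_plus.channel_labels)
        only_plus = set(profile_plus.channel_labels) - set(profile_minus.channel_labels)
        raise ValueError(
            "profiles must share one montage (identical channel sets and order); "
            f"only in PUM-: {sorted(only_minus)}, only in PUM+: {sorted(only_plus)}"
        )
    if profile_minus.sign != profile_plus.sign:
        raise ValueError("profiles use different ΔE sign conventions")
    d_minus = np.asarray(profile_minus.delta_e, dtype=float)
    d_plus = np.asarray(profile_plus.delta_e, dtype=float)
    finite = np.isfinite(d_minus) & np.isfinite(d_plus)
    diffs = d_plus[finite] - d_minus[finite]
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero < 1:
        raise ValueError(
            f"pair {pair_label or '?'}: all ΔE differences are zero; "
            "the signed-rank test is undefined"
        )
    method = "exact" if n_nonzero <= _EXACT_LIMIT else "approx"
    res = sps.wilcoxon(
        diffs, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    summarize = np.nanmedian if summary == "median" else np.nanmean
    return PairComparison(
        pair_label=pair_label,
        n_channels=int(finite.sum()),
        wilcoxon_statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=None,
        delta_e_summary_minus=float(summarize(d_minus[finite])),
        delta_e_summary_plus=float(summarize(d_plus[finite])),
        sign=profile_minus.sign,
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), m defaulting to len(p_values)."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    return [float(min(1.0, m * pi)) for pi in p]


def classify_css_changes(records: pd.DataFrame) -> tuple[dict[str, int], pd.DataFrame]:
    """Classify awareness change per pair from CSS scores.

    Returns counts of {improved, unchanged, aggravated} pairs and a per-pair
    table with delta_css = CSS(PUM+) - CSS(PUM-).  Improvement means a lower
    CSS under pulvinar stimulation.
    """
    rows = []
    for pair, grp in records.groupby("pair_label", sort=False):
        by_cond = dict(zip(grp["condition"], grp["css"]))
        if set(by_cond) != {"PUM+", "PUM-"}:
            raise ValueError(f"pair {pair!r} lacks one condition (has {sorted(by_cond)})")
        delta = int(by_cond["PUM+"]) - int(by_cond["PUM-"])
        label = "improved" if delta < 0 else ("aggravated" if delta > 0 else "unchanged")
        rows.append({"pair_label": pair, "delta_css": delta, "change": label})
    per_pair = pd.DataFrame(rows)
    counts = {
        k: int((per_pair["change"] == k).sum()) for k in ("improved", "unchanged", "aggravated")
    }
    return counts, per_pair


def correlate_css_deltaE(
    pair_deltas_css,
    pair_deltas_deltaE,
    method: str = "t",
) -> CorrelationResult:
    """Spearman rank correlation of per-pair CSS change against ΔE change.

    Average ranks for ties; two-sided p-value from the t-distribution
    approximation (``method='t'``, standard at this sample size) or from exact
    permutation enumeration (``method='exact'``, n <= 9 only).
    """
    x = np.asarray(list(pair_deltas_css), dtype=float)
    y = np.asarray(list(pair_deltas_deltaE), dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} CSS deltas vs {y.size} ΔE deltas")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs for a defined correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one input; the rank correlation is undefined")
    if method == "t":
        res = sps.spearmanr(x, y)
        return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if x.size > 9:
        raise ValueError("exact permutation p-value supported only for n <= 9")
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in permutations(ry):
        rho = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return CorrelationResult(rho_obs, count / total, int(x.size))


#: parameter columns summarized per stimulation group
_GROUP_SPECS = {
    "1 Hz": dict(filter=("hip_freq_hz", 1), amp="hip_amp_ma", dur="hip_dur_s"),
    "50 Hz": dict(filter=("hip_freq_hz", 50), amp="hip_amp_ma", dur="hip_dur_s"),
    "PUM": dict(filter=("condition", "PUM+"), amp="pum_amp_ma", dur="pum_dur_s"),
}


def summarize_stim_params(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Stimulation-parameter summary for one induction/stimulation group.

    Records are first deduplicated to distinct seizures (``seizure_id``);
    groups: '1 Hz' / '50 Hz' hippocampal inductions, 'PUM' pulvinar
    stimulations.  Reports n, mean, population SD (÷n, reproducing the
    printed-style "mean ± SD"), min and max per parameter, with mean/SD
    rounded to 2 decimals for display.
    """
    if group not in _GROUP_SPECS:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(_GROUP_SPECS)}")
    spec = _GROUP_SPECS[group]
    col, val = spec["filter"]
    sub = records.drop_duplicates("seizure_id")
    sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError(f"no distinct seizures in group {group!r}")
    rows = []
    for name, column in (("amplitude_ma", spec["amp"]), ("duration_s", spec["dur"])):
        v = sub[column].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": name,
                "n": int(v.size),
                "mean": round(float(v.mean()), 2),
                "sd_population": round(float(v.std(ddof=0)), 2),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)
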