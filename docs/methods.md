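# Methods

## Permutation entropy

The complexity measure is normalized Bandt–Pompe permutation entropy. A
series x of length N with embedding dimension D and delay τ yields
N − (D−1)τ vectors (x_t, x_{t+τ}, …, x_{t+(D−1)τ}); each vector is encoded as
the permutation of its indices that sorts it ascending. Equal values are
ranked by temporal order (the earlier sample ranks lower) — the classic
deterministic tie convention; no noise is added to break ties. PE is the
Shannon entropy of the relative pattern frequencies divided by log D!, which
makes the logarithm base irrelevant and bounds PE to [0, 1]. PE is exactly 0
iff a single pattern occurs (constant or monotone series) and is invariant
under positive affine maps and strictly increasing transforms of a tie-free
series — properties the test suite asserts, alongside exact equivalence with
a brute-force enumerator.

Defaults follow common SEEG practice: D = 3, τ = 1 sample, 5-s windows with a
2.5-s hop (50 % overlap). "2.5-s overlap" of 5-s windows is read as a 2.5-s
hop; for these values the two readings coincide. Seconds are converted to
samples by rounding half up. Windows start at t = 0, trailing samples that do
not fill a window are dropped, and the embedding never crosses a window
boundary. A window time stamp is its center (start + window/2). At 256 Hz a
5-s window holds 1278 vectors for 6 possible patterns, ample for a stable
estimate. Any non-finite sample poisons its windows (their PE is NaN for that
channel); missing signal is never interpolated.

## Montage and input formats

All analyses run on nonartifacted channels in an adjacent-contact bipolar
montage: for each electrode (letter prefix, primes allowed, e.g. B, H, B'),
contacts with consecutive indices form pairs, anode = lower index, ordered by
electrode then index. The sign choice is cosmetic — PE is sign-invariant —
but fixed for reproducibility. Artifact exclusion is an explicit user list of
contacts or pair names, never automatic detection: rejection criteria are a
curation decision that silent automation would make unauditable. Seizures of
one patient must be analyzed on the same montage; the pair comparison
enforces identical channel sets.

Recordings are EDF (read via MNE, returned in physical µV; mixed per-signal
sampling rates are rejected; annotation channels dropped). Event markers
travel in a sidecar TSV (label, onset_s, duration_s): `baseline_end`
(disconnection of the stimulated contacts), `stim_on`, `seizure_onset`,
`pulvinar_pulse_k`, `seizure_offset`; unknown labels pass through. The
package writes its own minimal 16-bit EDF (symmetric physical bounds per
channel, 1-s records for integral rates), so the simulator's output
round-trips through the standard reader within one quantization step.

## Delta Entropy

Windows are assigned to periods by center containment: baseline = centers in
[baseline_end − 7 s, baseline_end) — right-open because the marker starts the
artifacted disconnection epoch — and ictal = centers in [onset, offset].
Center assignment is unbiased for 50 %-overlapping windows and keeps both of
the ~2 baseline windows that full containment would lose. Per channel,
ΔE = mean baseline PE − minimum ictal PE. The drop convention (rather than
the literal minimum-minus-baseline difference) makes ΔE positive when
complexity is lost, which is the direction every downstream statement uses;
the literal convention is a switch, and serialized profiles record which was
used. Windows overlapping pulvinar pulses stay in the ictal set — the
entropy restoration during stimulation is part of the measured effect — while
an option can exclude windows overlapping any labeled interval (e.g. the
inducing hippocampal stimulation) for sensitivity analyses. Empty baseline or
ictal window sets are errors, never silent NaNs; channels without finite
values are flagged with a warning and excluded downstream.

## Statistics

Per pair, per-channel ΔE differences (PUM+ − PUM−) enter a two-sided Wilcoxon
signed-rank test: zero differences dropped (Wilcoxon's original convention),
exact null distribution up to 25 nonzero differences, normal approximation
with continuity correction beyond. Bonferroni correction uses
p_adj = min(1, m·p) with m defaulting to the number of pairs in the run.
Spearman's ρ uses average ranks for ties and a two-sided p from the
t-approximation, standard at n ≈ 11; an exact permutation p is available for
n ≤ 9. The per-seizure ΔE scalar entering the correlation is the median
across channels (mean available): the median is robust to the handful of
channels near the focus that dominate the drop. Stimulation-parameter
summaries deduplicate to distinct seizures first and report population
(÷ n) standard deviations, the convention that reproduces the source table's
group summaries exactly; means/SDs are rounded to two decimals for display.

## Synthetic data

The generator imposes a known ordinal-complexity structure per bipolar
channel — PE is amplitude-invariant, so all control is via waveform shape,
never gain:

- **Baseline / stimulation epoch / postictal:** unit-variance pink (1/f)
  noise, spectrally shaped white noise per channel. Pink noise mimics the
  broadband physiological EEG spectrum; at 256 Hz and D = 3 its PE is ≈ 0.99.
- **Ictal discharge:** (1 − f)·rhythm + f·noise, where the rhythm is a
  sinusoid at `ictal_freq_hz` (default 7 Hz, a typical theta-range discharge)
  plus a second harmonic at half amplitude and a per-channel random phase,
  and f = `ictal_noise_fraction` (default 0.1, giving windowed ictal PE
  ≈ 0.66). f = 1 degenerates to pure noise (no imposed drop), f = 0 to the
  pure rhythm (PE ≈ 0.49); the f → PE map is monotone and is inverted by
  bisection (`noise_fraction_for_drop`) to impose a target entropy drop.
- **Pulvinar pulses:** intervals of the ictal segment blended with fresh
  noise by `pulse_restoration` r: x ← (1 − r)·x + r·noise. r = 0 leaves the
  signal bit-identical; r = 1 restores baseline-level complexity. Pulse noise
  comes from an RNG stream independent of the background, so adding pulses or
  changing r never perturbs non-pulse samples — which also guarantees that
  restoration can only raise the ictal minimum, i.e. never increase ΔE.
- **Ground truth:** whole-segment PE (D = 3, τ = 1) of the generated baseline
  and of the pulse-free ictal samples, per channel; the imposed drop is their
  difference. The recovery tests compare the windowed pipeline ΔE against
  this independent whole-segment measurement (tolerance ±0.05, dominated by
  the minimum-over-windows statistic sitting slightly below the segment
  mean).

The sampling rate defaults to 256 Hz (typical clinical decimation; never
stated in the source) and everything is driven by one integer seed:
identical parameters and seed give bit-identical arrays.

`simulate_study` builds a full synthetic study mirroring the clinical table:
one recording per distinct seizure (19 across 11 pairs, with the "bis"
reuse structure of the table), baseline 15 s, induction and ictal durations
taken from the table (optionally scaled), and an imposed drop of
`base_drop + css_gain·css` (defaults 0.25 + 0.03·CSS). Tying the drop to each
seizure's CSS score encodes the studied coupling — deeper complexity loss
with worse awareness — and makes the pair-level ΔΔE proportional to ΔCSS by
construction, including for reused seizures. An optional per-seizure jitter
(`drop_jitter_sd`, default 0) weakens that proportionality for sensitivity
analyses. PUM+ seizures get one or two restoration pulses confined to the
second half of the ictal period, so the windowed ictal minimum (and hence the
imposed drop) is measured from pulse-free windows.

What the simulator does **not** emulate: electrode geometry and volume
conduction, true referential recordings (channels are generated directly as
bipolar derivations, since ground truth is imposed per analyzed channel),
artifact families (muscle, blinks), nonstationary seizure evolution
(frequency glides, postictal suppression), or between-channel correlation.
Passing tests therefore demonstrate that the pipeline measures imposed
ordinal structure correctly and that the statistics behave as specified —
not that clinical recordings would yield any particular effect size.

## Numerical and design choices

- Pattern counting is vectorized (argsort of a strided view, base-D codes,
  bincount per window); exact agreement with brute-force enumeration is an
  acceptance test, and 0·log 0 ≡ 0 by construction.
- Entropy/profile CSVs are reloaded with round-trip float parsing, so
  re-running downstream stages from saved intermediates is bit-identical.
- The pair-level scalar for the correlation (median vs mean across channels)
  and the Bonferroni m are explicit configuration, since reasonable analyses
  differ here.
- Test and acceptance problem sizes (4–8 channels, half-scale durations,
  8–10 study seeds) are desk-scale choices: PE at these sizes is estimated
  from ≥ 1200 vectors per window, and the study-level statistics are already
  stable, as the acceptance reruns across seeds show.

## Known limitations

- The exact Wilcoxon path is limited to ≤ 25 nonzero differences (scipy's
  exact null); larger montages use the corrected normal approximation.
- EDF writing pads non-integral final records only when the sampling rate is
  integral; arbitrary rates fall back to a single data record.
- ΔE with very short baselines rests on ~2 windows; the baseline-mean
  estimate is accordingly noisy and the package refuses empty sets rather
  than extrapolating.
- The correlation treats pairs as independent although "bis" pairs share a
  seizure with their base pair, mirroring the source analysis.
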