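# seegpe

Permutation-entropy complexity analysis of stimulation-induced SEEG seizures.

Loss of awareness during temporal-lobe seizures goes hand in hand with a loss
of cortical signal complexity: intracranial EEG becomes rhythmic and ordinally
predictable while consciousness is impaired. `seegpe` implements the analysis
chain used to quantify that effect and to test whether high-frequency
stimulation of the medial pulvinar nucleus (PUM) of the thalamus preserves
complexity — and with it, awareness — in hippocampus-induced seizures:

1. **Windowed permutation entropy (PE).** Each length-*D* embedding vector
   (x_t, x_{t+τ}, …, x_{t+(D−1)τ}) of a bipolar SEEG channel is mapped to the
   permutation that sorts it ascending (ties broken by temporal order); PE is
   the Shannon entropy of the pattern distribution normalized by log *D*!, so
   PE ∈ [0, 1] with 0 for a regular series and 1 for a random one. Defaults:
   D = 3, τ = 1 sample, 5-s sliding windows with a 2.5-s hop.
2. **Delta Entropy (ΔE).** Per channel, ΔE = mean baseline PE − minimum ictal
   PE, with the baseline taken as the 7 s before the stimulated contacts were
   disconnected and the ictal period bounded by the seizure onset/offset
   markers. ΔE is the depth of the complexity drop (a literal
   minimum-minus-baseline sign convention is available as a switch).
3. **Paired statistics.** Matched seizure pairs — the same patient induced
   without (PUM−) and with (PUM+) pulvinar stimulation, analyzed on the same
   bipolar montage — are compared channel-wise with a two-sided Wilcoxon
   signed-rank test (exact null up to 25 nonzero differences), Bonferroni
   corrected across pairs. Awareness is scored with the Consciousness Seizure
   Scale (CSS, 0–9, higher = more impaired); the coupling between awareness
   change and complexity change is Spearman's ρ of per-pair
   ΔCSS = CSS(PUM+) − CSS(PUM−) against ΔΔE = ΔE(PUM+) − ΔE(PUM−).

Because the clinical recordings are not publicly deposited, the package ships
a synthetic seizure generator (`seegpe.simulate`) with known, per-channel
ground-truth complexity structure, plus the study's clinical-parameters table
(stimulation settings, seizure durations and CSS scores of the 11 matched
pairs), so the entire pipeline is testable end to end.

Intended users: clinical-neurophysiology and epilepsy researchers analyzing
windowed signal-complexity changes around ictal events, and anyone needing a
tested, reproducible PE/ΔE reference implementation.

## Worked example

```python
import dataclasses
from seegpe import (SimulationParams, simulate_seizure_recording, sliding_window_pe,
                    compute_delta_entropy, permutation_entropy)
from seegpe.simulate import noise_fraction_for_drop

# the PE of a 7-sample toy series (patterns {012: 2, 201: 2, 102: 1} of 5 vectors)
print(round(permutation_entropy((4, 7, 9, 10, 6, 11, 3)), 4))       # 0.5888

# simulate a 4-channel seizure whose ictal discharge imposes a 0.45 entropy drop
params = SimulationParams(n_channels=4, seed=1)
frac = noise_fraction_for_drop(0.45, params)                         # 0.0078
rec, timeline, truth = simulate_seizure_recording(
    dataclasses.replace(params, ictal_noise_fraction=frac))
matrix = sliding_window_pe(rec)                                      # shape (4, 31)
profile = compute_delta_entropy(matrix, timeline)
for lab, b, m, d, t in zip(profile.channel_labels, profile.baseline_mean,
                           profile.ictal_min, profile.delta_e, truth.drop):
    print(f"{lab}: baseline {b:.3f}  ictal min {m:.3f}  dE {d:.3f}  (imposed {t:.3f})")
```

prints

```
B1-B2: baseline 0.993  ictal min 0.525  dE 0.468  (imposed 0.448)
B2-B3: baseline 0.991  ictal min 0.520  dE 0.472  (imposed 0.451)
B3-B4: baseline 0.989  ictal min 0.534  dE 0.455  (imposed 0.447)
B4-B5: baseline 0.989  ictal min 0.519  dE 0.469  (imposed 0.454)
```

Baseline pink noise sits near the random limit (PE ≈ 0.99), the rhythmic
discharge drops each channel's windowed minimum to ≈ 0.52, and the recovered
per-channel ΔE matches the imposed drop within the windowing tolerance.

The same analysis runs from the shell:

```bash
seegpe simulate --seed 1 --channels 8 --out study/      # synthetic study (11 pairs)
seegpe run --study study/ --out results/                # PE, ΔE, stats, figures
seegpe fixture --out table1.csv                         # clinical-parameters table
```

`results/` then contains one entropy CSV, ΔE CSV, heatmap and global-curve
figure per seizure, the per-pair Wilcoxon table, the CSS-change
classification, the CSS–ΔE correlation JSON and per-pair ΔE boxplots, plus a
run manifest for bit-identical re-runs.

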