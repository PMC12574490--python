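"""Paired Wilcoxon, Bonferroni, CSS classification and rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seegpe import (
    DeltaEntropyProfile,
    bonferroni,
    classify_css_changes,
    compare_pair,
    correlate_css_deltaE,
    make_table1_fixture,
    summarize_stim_params,
)


def _profile(drops, labels=None):
    drops = np.asarray(drops, dtype=float)
    labels = labels or [f"c{i}" for i in range(drops.size)]
    return DeltaEntropyProfile(
        channel_labels=labels,
        baseline_mean=np.full(drops.size, 0.95),
        ictal_min=0.95 - drops,
        n_baseline_windows=2,
        n_ictal_windows=10,
    )


def exact_signed_rank_p(diffs):
    """Two-sided signed-rank p by full 2^n sign enumeration (independent oracle)."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    mu = ranks.sum() / 2
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestComparePair:
    def test_six_uniform_signs_exact_p(self):
        """Six channels, all differences one sign: exact two-sided p = 2/2^6."""
        cmp_ = compare_pair(_profile([0.45] * 6), _profile([0.25, 0.3, 0.2, 0.35, 0.15, 0.4]))
        assert cmp_.p_raw == pytest.approx(0.03125)
        assert cmp_.n_channels == 6

    def test_self_comparison_undefined(self):
        p = _profile([0.4, 0.3, 0.2])
        with pytest.raises(ValueError, match="zero"):
            compare_pair(p, p)

    def test_mismatched_channels_listed(self):
        a = _profile([0.4, 0.3], labels=["B1-B2", "B2-B3"])
        b = _profile([0.4, 0.3], labels=["B1-B2", "H1-H2"])
        with pytest.raises(ValueError, match="H1-H2"):
            compare_pair(a, b)

    def test_exact_p_matches_sign_enumeration(self):
        """Exact Wilcoxon p agrees with full 2^n enumeration on random inputs."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            diffs = rng.standard_normal(n) * 0.1 + 0.05
            base = rng.uniform(0.2, 0.5, size=n)
            cmp_ = compare_pair(_profile(base), _profile(base + diffs))
            assert cmp_.p_raw == pytest.approx(exact_signed_rank_p(diffs), abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha = 0.05 stays within [0.03, 0.07]."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(0.35, 0.05, size=20)
            b = rng.normal(0.35, 0.05, size=20)
            rejections += compare_pair(_profile(a), _profile(b)).p_raw < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_power_at_simulated_effect(self):
        """Attenuation of 0.3 on 20 channels (noise sd 0.05): p < 0.05 in >= 90%."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            minus = rng.normal(0.45, 0.05, size=20)
            plus = rng.normal(0.15, 0.05, size=20)
            hits += compare_pair(_profile(minus), _profile(plus)).p_raw < 0.05
        assert hits >= 90

    def test_summary_statistic_choice(self):
        a, b = _profile([0.1, 0.2, 0.9]), _profile([0.0, 0.1, 0.2])
        med = compare_pair(a, b, summary="median")
        mean = compare_pair(a, b, summary="mean")
        assert med.delta_e_summary_minus == pytest.approx(0.2)
        assert mean.delta_e_summary_minus == pytest.approx(0.4)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [([0.003], 11, [0.033]), ([0.2], 11, [1.0]), ([0.04, 0.2], 1, [0.04, 0.2])],
    )
    def test_examples(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_m_defaults_to_count(self):
        assert bonferroni([0.01, 0.02]) == pytest.approx([0.02, 0.04])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = bonferroni(p, 11)
        assert np.all(np.asarray(adj) >= p - 1e-15)
        assert np.all(np.asarray(adj) <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestCssClassification:
    def test_fixture_counts(self):
        """The clinical table yields 5 improved, 5 unchanged, 1 aggravated pairs."""
        counts, per_pair = classify_css_changes(make_table1_fixture())
        assert counts == {"improved": 5, "unchanged": 5, "aggravated": 1}
        assert sum(counts.values()) == per_pair.shape[0] == 11

    def test_p4bis_delta(self):
        _, per_pair = classify_css_changes(make_table1_fixture())
        assert per_pair.set_index("pair_label").loc["P4bis", "delta_css"] == -9

    def test_all_equal_css(self):
        df = pd.DataFrame(
            {
                "pair_label": ["a", "a", "b", "b"],
                "condition": ["PUM+", "PUM-"] * 2,
                "css": [3, 3, 0, 0],
            }
        )
        counts, _ = classify_css_changes(df)
        assert counts == {"improved": 0, "unchanged": 2, "aggravated": 0}

    def test_incomplete_pair_rejected(self):
        df = pd.DataFrame({"pair_label": ["a"], "condition": ["PUM+"], "css": [3]})
        with pytest.raises(ValueError, match="a"):
            classify_css_changes(df)


class TestSpearman:
    def test_monotone_toys(self):
        x = list(range(8))
        y = [v * 0.1 for v in x]
        assert correlate_css_deltaE(x, y).rho == pytest.approx(1.0)
        assert correlate_css_deltaE(x, y[::-1]).rho == pytest.approx(-1.0)
        r = correlate_css_deltaE([-2, -1, 0, 1, 2], [-0.2, -0.1, 0, 0.1, 0.2])
        assert r.rho == pytest.approx(1.0)

    def test_equals_pearson_of_average_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.integers(-3, 4, size=12).astype(float)  # ties likely
        y = rng.standard_normal(12)
        if np.ptp(x) == 0:
            x[0] += 1
        rho = correlate_css_deltaE(x, y).rho
        pearson = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)

    def test_exact_permutation_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0.1, 0.3, 0.2, 0.5, 0.4, 0.9]
        exact = correlate_css_deltaE(x, y, method="exact")
        assert exact.rho == pytest.approx(correlate_css_deltaE(x, y).rho)
        assert 0.0 < exact.p_value <= 1.0
        # perfectly monotone: only the 2 extreme orderings are as extreme
        perfect = correlate_css_deltaE(x, sorted(y), method="exact")
        assert perfect.p_value == pytest.approx(2 / 720)

    @pytest.mark.parametrize(
        "x, y, msg",
        [
            ([1, 2], [1, 2], "at least 3"),
            ([1, 1, 1], [1, 2, 3], "zero variance"),
            ([1, 2, 3], [1, 2], "mismatch"),
        ],
    )
    def test_validation(self, x, y, msg):
        with pytest.raises(ValueError, match=msg):
            correlate_css_deltaE(x, y)


class TestStimParamSummaries:
    def test_high_frequency_group(self):
        """Printed 50-Hz induction summary recomputed from the six distinct rows."""
        s = summarize_stim_params(make_table1_fixture(), "50 Hz").set_index("parameter")
        amp = s.loc["amplitude_ma"]
        assert (amp["n"], amp["mean"], amp["sd_population"]) == (6, 1.43, 0.35)
        assert (amp["min"], amp["max"]) == (0.8, 1.8)
        dur = s.loc["duration_s"]
        assert (dur["mean"], dur["sd_population"]) == (4.67, 0.47)
        assert (dur["min"], dur["max"]) == (4.0, 5.0)

    def test_pulvinar_group(self):
        """Printed pulvinar stimulation summary: 9 distinct stimulations."""
        s = summarize_stim_params(make_table1_fixture(), "PUM").set_index("parameter")
        amp = s.loc["amplitude_ma"]
        assert (amp["n"], amp["mean"], amp["sd_population"]) == (9, 1.44, 0.5)
        assert (amp["min"], amp["max"]) == (1.0, 2.0)
        dur = s.loc["duration_s"]
        assert (dur["mean"], dur["sd_population"]) == (5.8, 1.23)

    def test_single_element_group(self):
        df = pd.DataFrame(
            {
                "seizure_id": ["s1"],
                "hip_freq_hz": [50],
                "condition": ["PUM-"],
                "hip_amp_ma": [1.5],
                "hip_dur_s": [5.0],
            }
        )
        s = summarize_stim_params(df, "50 Hz").set_index("parameter")
        assert s.loc["amplitude_ma", "sd_population"] == 0.0
        assert (s.loc["amplitude_ma", "min"], s.loc["amplitude_ma", "max"]) == (1.5, 1.5)

    def test_empty_group_rejected(self):
        df = pd.DataFrame(
            {"seizure_id": ["s1"], "hip_freq_hz": [50], "condition": ["PUM-"],
             "hip_amp_ma": [1.5], "hip_dur_s": [5.0]}
        )
        with pytest.raises(ValueError, match="1 Hz"):
            summarize_stim_params(df, "1 Hz")
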