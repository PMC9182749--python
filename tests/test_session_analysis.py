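"""Frequencies, sections, VO2max correlation and group tests."""

import numpy as np
import pytest
from scipy import stats

from hbregimes.session_analysis import (
    SessionClusterSummary,
    cluster_frequencies,
    correlate_vo2max,
    group_tests,
    nonoverlapping_subset,
    p_value_stars,
    section_frequencies,
)


class TestFrequencies:
    def test_counting_example(self):
        s = cluster_frequencies(["-/+", "-/+", "-/-", "+/+"])
        assert s.frequencies["-/+"] == 0.5
        assert s.frequencies["-/-"] == 0.25
        assert s.frequencies["+/+"] == 0.25
        assert s.frequencies["+/-"] == 0.0

    def test_single_label(self):
        s = cluster_frequencies(["+/-"] * 7)
        assert s.frequencies["+/-"] == 1.0
        assert sum(s.frequencies.values()) == pytest.approx(1.0)

    def test_sum_to_one_random(self, rng):
        labels = rng.choice(["+/+", "+/-", "-/+", "-/-"], 101)
        s = cluster_frequencies(labels.tolist())
        assert sum(s.frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cluster_frequencies([])

    def test_permutation_equivariance(self, rng):
        labels = rng.choice(["+/+", "-/-"], 50).tolist()
        f1 = cluster_frequencies(labels).frequencies
        rng.shuffle(labels)
        f2 = cluster_frequencies(labels).frequencies
        assert f1 == f2


class TestNonoverlapping:
    def test_stride_example(self):
        starts = np.arange(91.0)  # starts 0..90 s of 90 s windows
        keep = nonoverlapping_subset(starts, 90.0)
        assert starts[keep].tolist() == [0.0, 90.0]

    def test_single_window(self):
        assert nonoverlapping_subset([12.0], 90.0).tolist() == [True]

    def test_pairwise_disjoint(self, rng):
        starts = np.sort(rng.uniform(0, 2000, 300))
        kept = starts[nonoverlapping_subset(starts, 90.0)]
        assert np.all(np.diff(kept) >= 90.0)

    def test_count_formula_on_gapfree_run(self):
        for n_starts in (91, 180, 361):
            starts = np.arange(float(n_starts))
            kept = nonoverlapping_subset(starts, 90.0)
            assert kept.sum() == (n_starts - 1) // 90 + 1


class TestSections:
    def test_all_in_first_third(self):
        starts = np.arange(0.0, 100.0, 10.0)
        labels = ["-/-"] * 10
        out = section_frequencies(starts, labels, 90.0, 600.0)
        assert out[0].frequencies["-/-"] == 1.0
        assert out[1].n_windows == 0 or out[1].frequencies is None

    def test_midpoint_boundary_rule(self):
        # midpoint (start + 45) / duration decides the section
        duration = 300.0
        out = section_frequencies([54.0], ["+/+"], 90.0, duration)
        # midpoint 99 -> 0.33 -> falls in 'start' if < 1/3, middle otherwise
        sec_of_window = [s for s in out if s.n_windows == 1][0].section
        assert sec_of_window == ("start" if 99.0 / duration < 1 / 3 else "middle")

    def test_empty_section_flagged(self):
        with pytest.warns(UserWarning, match="no windows"):
            out = section_frequencies([10.0], ["+/+"], 90.0, 900.0)
        assert out[2].frequencies is None

    def test_recomposition(self, rng):
        starts = np.sort(rng.uniform(0, 800, 200))
        labels = rng.choice(["+/+", "+/-", "-/+", "-/-"], 200).tolist()
        out = section_frequencies(starts, labels, 90.0, 900.0)
        total = cluster_frequencies(labels).frequencies
        for lab in total:
            weighted = sum(
                s.frequencies[lab] * s.n_windows for s in out if s.frequencies
            ) / len(labels)
            assert weighted == pytest.approx(total[lab], abs=1e-12)

    def test_uniform_labels_even_sections(self, rng):
        starts = np.arange(0.0, 300.0)
        labels = rng.choice(["+/+", "-/-"], 300).tolist()
        out = section_frequencies(starts, labels, 90.0, 390.0)
        counts = np.array([
            [s.n_windows * s.frequencies[lab] for lab in ("+/+", "-/-")]
            for s in out
        ])
        chi2 = stats.chi2_contingency(counts)
        assert chi2.pvalue > 0.05


def _summary(i, freqs, vo2):
    return SessionClusterSummary(f"s{i}", "2021-01-01", freqs, 100, vo2)


class TestVO2maxCorrelation:
    def test_perfect_linear(self):
        sums = [
            _summary(i, {"+/+": 0.1, "+/-": 0.2, "-/+": 0.1 + 0.05 * i,
                         "-/-": 0.6 - 0.05 * i}, 30.0 + i)
            for i in range(6)
        ]
        rep = correlate_vo2max(sums)
        r, p, n = rep.per_label["-/+"]
        assert r == pytest.approx(1.0)
        assert rep.per_label["-/-"][0] == pytest.approx(-1.0)

    def test_permuted_mostly_null(self):
        base = np.linspace(0.1, 0.4, 10)
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            vo2 = r.permutation(np.linspace(30, 40, 10))
            sums = [
                _summary(i, {"+/+": 1 - base[i], "+/-": 0.0, "-/+": base[i],
                             "-/-": 0.0}, vo2[i])
                for i in range(10)
            ]
            rep = correlate_vo2max(sums)
            hits += rep.per_label["-/+"][1] > 0.05
        assert hits >= 85

    def test_missing_vo2_excluded(self):
        sums = [_summary(i, {"+/+": 0.2 + 0.1 * i, "+/-": 0.8 - 0.1 * i,
                             "-/+": 0.0, "-/-": 0.0},
                         32.0 + i if i else None) for i in range(5)]
        with pytest.warns(UserWarning, match="excluded"):
            rep = correlate_vo2max(sums)
        assert rep.per_label["+/+"][2] == 4

    def test_constant_frequency_flagged(self):
        sums = [_summary(i, {"+/+": 0.25, "+/-": 0.25, "-/+": 0.25 + 0.01 * i,
                             "-/-": 0.25 - 0.01 * i}, 30.0 + i) for i in range(4)]
        with pytest.warns(UserWarning, match="undefined"):
            rep = correlate_vo2max(sums)
        assert np.isnan(rep.per_label["+/+"][0])

    def test_too_few_sessions(self):
        with pytest.raises(ValueError):
            correlate_vo2max([_summary(0, {"+/+": 1.0}, 30.0)] * 2)


class TestGroupTests:
    def test_identical_groups_null(self, rng):
        g = rng.standard_normal(30)
        rep = group_tests({"a": g, "b": g.copy(), "c": g.copy()})
        assert rep.pvalue > 0.9
        assert not rep.significant
        assert (rep.posthoc["p_adj"] > 0.5).all()

    def test_shifted_groups_detected(self):
        hits = 0
        for s in range(30):
            r = np.random.default_rng(s)
            rep = group_tests({"a": r.standard_normal(30),
                               "b": 3.0 + r.standard_normal(30)})
            hits += rep.significant and (rep.posthoc["p_adj"] < 0.05).all()
        assert hits == 30

    def test_normality_gate_switches_test(self, rng):
        normal = {"a": rng.standard_normal(40), "b": rng.standard_normal(40)}
        skewed = {"a": rng.exponential(1.0, 40) ** 2,
                  "b": rng.exponential(1.0, 40) ** 2}
        assert group_tests(normal).omnibus_test == "anova"
        rep = group_tests(skewed)
        assert rep.omnibus_test == "kruskal-wallis"
        assert (rep.posthoc["test"] == "mann-whitney").all()

    def test_bonferroni_formula(self, rng):
        groups = {k: rng.exponential(1.0, 25) ** 2 for k in "abc"}
        rep = group_tests(groups)
        m = len(rep.posthoc)
        for _, row in rep.posthoc.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, m * row["p_raw"]))

    def test_repeated_design(self, rng):
        base = rng.standard_normal(12)
        groups = {
            "start": base + rng.normal(0, 0.2, 12),
            "middle": base + 0.5 + rng.normal(0, 0.2, 12),
            "end": base + 1.2 + rng.normal(0, 0.2, 12),
        }
        rep = group_tests(groups, design="repeated")
        assert rep.omnibus_test in ("rm-anova", "friedman")
        assert rep.significant

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            group_tests({"a": np.ones(5), "b": np.arange(5.0)})


def test_p_value_stars_bins():
    assert p_value_stars(0.2) == "ns"
    assert p_value_stars(0.03) == "*"
    assert p_value_stars(0.005) == "**"
    assert p_value_stars(5e-4) == "***"
    assert p_value_stars(1e-5) == "****"
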