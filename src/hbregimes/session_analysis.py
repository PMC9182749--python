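"""Session- and cohort-level statistics of the regime labels.

Covers: per-session regime frequencies (over all overlapping windows),
a greedy non-overlapping window subset for statistically independent
points, start/middle/end section frequencies on normalized session time,
the Pearson association between regime frequencies and VO2max across
sessions, and omnibus + post-hoc group tests gated on normality.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import SIGN_LABELS

__all__ = [
    "SECTIONS",
    "SessionClusterSummary",
    "SectionSummary",
    "CorrelationReport",
    "GroupTestReport",
    "cluster_frequencies",
    "nonoverlapping_subset",
    "section_frequencies",
    "correlate_vo2max",
    "group_tests",
    "p_value_stars",
]

SECTIONS = ("start", "middle", "end")


@dataclass
class SessionClusterSummary:
    session_id: str
    date: str
    frequencies: dict  # sign label -> fraction
    n_windows: int
    vo2max: float | None = None


@dataclass
class SectionSummary:
    section: str
    frequencies: dict | None  # None when the section holds no windows
    n_windows: int
    det: float | None = None


@dataclass
class CorrelationReport:
    per_label: dict  # label -> (r, p, n)


@dataclass
class GroupTestReport:
    omnibus_test: str
    statistic: float
    pvalue: float
    normal: bool
    shapiro_pvalues: dict
    posthoc: pd.DataFrame
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.pvalue < 0.05)


def p_value_stars(p: float) -> str:
    """Significance annotation bins (ns, *, **, ***, ****)."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def cluster_frequencies(labels, session_id: str = "", date: str = "",
                        vo2max: float | None = None) -> SessionClusterSummary:
    """Fraction of windows per sign label; absent labels get 0."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labeled windows")
    n = len(labels)
    freqs = {lab: labels.count(lab) / n for lab in SIGN_LABELS}
    for lab in set(labels) - set(SIGN_LABELS):
        freqs[lab] = labels.count(lab) / n
    return SessionClusterSummary(session_id=session_id, date=date,
                                 frequencies=freqs, n_windows=n, vo2max=vo2max)


def nonoverlapping_subset(window_starts, width_s: float) -> np.ndarray:
    """Greedy selection of pairwise-disjoint windows.

    Starting from the first window, keep each window whose start is at
    least ``width_s`` after the last kept start.  Returns the boolean mask
    of kept windows (input must be sorted by start).
    """
    starts = np.asarray(window_starts, dtype=float)
    if np.any(np.diff(starts) < 0):
        raise ValueError("window starts must be sorted")
    keep = np.zeros(starts.size, dtype=bool)
    last = -np.inf
    for i, s in enumerate(starts):
        if s - last >= width_s:
            keep[i] = True
            last = s
    return keep


def section_frequencies(window_starts, labels, width_s: float,
                        duration_s: float, dets: dict | None = None) -> list:
    """Regime frequencies in the start/middle/end thirds of the session.

    A window belongs to the section containing its midpoint on time
    normalized to [0, 1].  A section without windows is flagged (``None``
    frequencies) rather than failing.
    """
    starts = np.asarray(window_starts, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if starts.size != labels.size:
        raise ValueError("starts/labels length mismatch")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    mid = (starts + width_s / 2.0) / duration_s
    section_idx = np.clip((mid * 3).astype(int), 0, 2)
    out = []
    for j, name in enumerate(SECTIONS):
        sel = labels[section_idx == j]
        if sel.size == 0:
            warnings.warn(f"section {name!r} holds no windows", stacklevel=2)
            out.append(SectionSummary(section=name, frequencies=None, n_windows=0,
                                      det=(dets or {}).get(name)))
            continue
        freqs = {lab: float(np.mean(sel == lab)) for lab in SIGN_LABELS}
        out.append(SectionSummary(section=name, frequencies=freqs,
                                  n_windows=int(sel.size),
                                  det=(dets or {}).get(name)))
    return out


def correlate_vo2max(summaries: list) -> CorrelationReport:
    """Pearson r between per-session regime frequency and VO2max.

    Sessions without a VO2max value are dropped with a warning; at least 3
    remaining sessions are required.  Constant frequency (or constant
    VO2max) leaves r undefined (NaN, flagged).
    """
    with_v = [s for s in summaries if s.vo2max is not None]
    if len(with_v) < len(summaries):
        warnings.warn("sessions without vo2max excluded from correlation",
                      stacklevel=2)
    if len(with_v) < 3:
        raise ValueError("need >= 3 sessions with vo2max")
    v = np.array([s.vo2max for s in with_v])
    per_label = {}
    for lab in SIGN_LABELS:
        f = np.array([s.frequencies.get(lab, 0.0) for s in with_v])
        if np.ptp(f) == 0 or np.ptp(v) == 0:
            warnings.warn(f"correlation undefined for {lab} (constant input)",
                          stacklevel=2)
            per_label[lab] = (float("nan"), float("nan"), len(with_v))
            continue
        r, p = stats.pearsonr(f, v)
        per_label[lab] = (float(r), float(p), len(with_v))
    return CorrelationReport(per_label=per_label)


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def group_tests(groups: dict, design: str = "independent",
                alpha: float = 0.05) -> GroupTestReport:
    """Omnibus + post-hoc comparison of feature values across groups.

    The omnibus test is a one-way ANOVA when every group passes the
    Shapiro-Wilk normality check at ``alpha``, otherwise Kruskal-Wallis.
    Post-hoc pairwise tests are Tukey HSD (normal, independent), paired
    t-tests (normal, repeated), Mann-Whitney U (non-normal, independent) or
    Wilcoxon signed-rank (non-normal, repeated); non-Tukey p-values get a
    Bonferroni adjustment over the number of pairs.  ``repeated`` designs
    require equal-length groups ordered by subject (here: session).
    """
    if design not in ("independent", "repeated"):
        raise ValueError("design must be 'independent' or 'repeated'")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if a.size < 3:
            raise ValueError(f"group {n!r} has fewer than 3 observations")
        if np.ptp(a) == 0:
            raise ValueError(f"group {n!r} is degenerate (constant)")
    if design == "repeated" and len({a.size for a in arrays}) != 1:
        raise ValueError("repeated design needs equal group sizes")

    shapiro_p = {n: float(stats.shapiro(a).pvalue) for n, a in zip(names, arrays)}
    normal = all(p > alpha for p in shapiro_p.values())

    if design == "independent":
        if normal:
            res = stats.f_oneway(*arrays)
            omnibus = "anova"
        else:
            res = stats.kruskal(*arrays)
            omnibus = "kruskal-wallis"
    else:
        if normal:
            # one-way repeated-measures ANOVA via the subject-blocked F test
            data = np.column_stack(arrays)
            n_subj, k = data.shape
            grand = data.mean()
            ss_cond = n_subj * np.sum((data.mean(axis=0) - grand) ** 2)
            ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
            ss_tot = np.sum((data - grand) ** 2)
            ss_err = ss_tot - ss_cond - ss_subj
            df1, df2 = k - 1, (k - 1) * (n_subj - 1)
            f = (ss_cond / df1) / (ss_err / df2)
            from collections import namedtuple

            _F = namedtuple("FTestResult", "statistic pvalue")
            res = _F(f, stats.f.sf(f, df1, df2))
            omnibus = "rm-anova"
        else:
            res = stats.friedmanchisquare(*arrays)
            omnibus = "friedman"

    pairs = list(itertools.combinations(range(len(names)), 2))
    m = len(pairs)
    rows = []
    if normal and design == "independent":
        tukey = stats.tukey_hsd(*arrays)
        for i, j in pairs:
            p_adj = float(tukey.pvalue[i, j])
            rows.append((names[i], names[j], "tukey-hsd", p_adj, p_adj))
    else:
        for i, j in pairs:
            if design == "independent":
                p_raw = float(stats.mannwhitneyu(arrays[i], arrays[j],
                                                 alternative="two-sided").pvalue)
                test = "mann-whitney"
            elif normal:
                p_raw = float(stats.ttest_rel(arrays[i], arrays[j]).pvalue)
                test = "paired-t"
            else:
                p_raw = float(stats.wilcoxon(arrays[i], arrays[j]).pvalue)
                test = "wilcoxon"
            rows.append((names[i], names[j], test, p_raw, _bonferroni(p_raw, m)))
    posthoc = pd.DataFrame(rows, columns=["group1", "group2", "test",
                                          "p_raw", "p_adj"])
    posthoc["stars"] = posthoc["p_adj"].map(p_value_stars)
    return GroupTestReport(
        omnibus_test=omnibus,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        normal=normal,
        shapiro_pvalues=shapiro_p,
        posthoc=posthoc,
    )
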