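"""Nonparametric test battery and summary statistics.

Routing is a pure function of (number of groups, paired flag): Wilcoxon
signed-rank for two paired samples, Friedman for more than two paired
samples, Kruskal-Wallis for more than two independent samples, with a
Tukey-style multiple comparison on mean ranks (studentized-range critical
values) after an omnibus rejection.  Anderson-Darling normality is reported
per group and the two-sample Kolmogorov-Smirnov test compares distributions.
Significance is declared at p < 0.05.  Scipy supplies every named test; this
module's contract is routing, post-hoc comparison, and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .io import ValidationError

__all__ = ["TestResult", "run_battery", "ks_compare", "summarize", "ALPHA"]

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    groups: list
    n_per_group: list
    significant: bool
    posthoc: list = field(default_factory=list)   # (label_i, label_j, p_adjusted)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0 <= self.p_value <= 1):
            raise ValidationError(f"p-value out of range: {self.p_value}")


def _rank_posthoc_independent(groups, labels) -> list:
    """Dunn/Nemenyi-style pairwise comparison on mean ranks after
    Kruskal-Wallis, using studentized-range critical values."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    mean_ranks = []
    i0 = 0
    for n in ns:
        mean_ranks.append(ranks[i0: i0 + n].mean())
        i0 += n
    out = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(big_n * (big_n + 1) / 12.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, np.inf))
        out.append((labels[i], labels[j], min(1.0, p)))
    return out


def _rank_posthoc_paired(groups, labels) -> list:
    """Nemenyi comparison on within-block mean ranks after Friedman."""
    k = len(groups)
    n = len(groups[0])
    data = np.column_stack(groups)
    ranks = sps.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    out = []
    for i, j in combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = float(sps.studentized_range.sf(q, k, np.inf))
        out.append((labels[i], labels[j], min(1.0, p)))
    return out


def run_battery(groups: list, paired: bool, labels: list | None = None) -> list[TestResult]:
    """Route the sample collection to the study's nonparametric battery.

    Returns the omnibus (or two-sample) result followed by per-group
    Anderson-Darling normality reports.
    """
    groups = [np.asarray(g, float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValidationError("run_battery needs >= 2 groups")
    if paired and len({len(g) for g in groups}) != 1:
        raise ValidationError("paired samples must have equal lengths")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    results: list[TestResult] = []
    ns = [len(g) for g in groups]

    if len(groups) == 2 and paired:
        diffs = groups[1] - groups[0]
        if np.all(diffs == 0):
            res = TestResult("wilcoxon_signed_rank", 0.0, 1.0, labels, ns, False)
            results.append(res)
        else:
            stat, p = sps.wilcoxon(groups[0], groups[1])
            results.append(TestResult("wilcoxon_signed_rank", float(stat), float(p),
                                      labels, ns, p < ALPHA))
    elif paired:
        stat, p = sps.friedmanchisquare(*groups)
        res = TestResult("friedman", float(stat), float(p), labels, ns, p < ALPHA)
        if res.significant:
            res.posthoc = _rank_posthoc_paired(groups, labels)
        results.append(res)
    elif len(groups) == 2:
        stat, p = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        results.append(TestResult("mann_whitney_u", float(stat), float(p),
                                  labels, ns, p < ALPHA))
    else:
        stat, p = sps.kruskal(*groups)
        res = TestResult("kruskal_wallis", float(stat), float(p), labels, ns, p < ALPHA)
        if res.significant:
            res.posthoc = _rank_posthoc_independent(groups, labels)
        results.append(res)

    for lab, g in zip(labels, groups):
        if np.unique(g).size < 3 or g.size < 4:
            continue
        ad = sps.anderson(g, dist="norm", method="interpolate")
        p = float(ad.pvalue)
        results.append(TestResult("anderson_darling_normality", float(ad.statistic),
                                  p, [lab], [g.size], p < ALPHA))
    return results


def ks_compare(a, b, labels=("a", "b")) -> TestResult:
    """Two-sample Kolmogorov-Smirnov comparison of distributions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    stat, p = sps.ks_2samp(a, b)
    return TestResult("kolmogorov_smirnov_2samp", float(stat), float(p),
                      list(labels), [a.size, b.size], p < ALPHA)


def summarize(values) -> tuple[float, float]:
    """Mean +/- standard error (SD / sqrt(n)); n >= 2 required."""
    v = np.asarray(values, float).ravel()
    if v.size < 2:
        raise ValidationError("standard error is undefined for n < 2")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
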