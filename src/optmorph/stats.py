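"""Group comparison layer for morphometric data.

Mirrors the conventional gated workflow for multi-group comparisons of cell
morphology metrics: Shapiro–Wilk normality per group decides between one-way
ANOVA with Bonferroni-corrected pairwise t-tests (all groups normal) and the
Kruskal–Wallis rank test with Dunn's pairwise z-tests (otherwise).  Two-group
mean comparisons use a t-test (Welch by default).  Significance at P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "normality_gate",
    "compare_parametric",
    "compare_nonparametric",
    "compare_auto",
    "two_group_ttest",
    "dunn_posthoc",
]


@dataclass
class GroupComparison:
    """Result of a multi-group comparison with pairwise post-hoc tests."""

    test_name: str  # "anova_bonferroni" or "kruskal_dunn"
    global_statistic: float
    global_p: float
    pairwise: list[tuple[str, str, float, bool]]  # (a, b, adjusted_p, significant)
    alpha: float = 0.05
    normality_ps: dict = field(default_factory=dict)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(g.ndim != 1 for g in out):
        raise ValueError("each group must be a 1D sequence")
    return out


def _labels(groups, labels) -> list[str]:
    if labels is None:
        return [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match the number of groups")
    return list(labels)


def normality_gate(groups, alpha: float = 0.05, labels=None):
    """Shapiro–Wilk p per group; parametric iff every group passes at alpha.

    Constant (zero-variance) groups are rejected: the Shapiro–Wilk statistic
    is undefined for them.
    Returns ``(per_group_p: dict, parametric_flag: bool)``.
    """
    gs = _as_groups(groups)
    names = _labels(gs, labels)
    ps = {}
    for name, g in zip(names, gs):
        if len(g) < 3:
            raise ValueError(f"{name}: Shapiro–Wilk needs n >= 3")
        if np.ptp(g) == 0:
            raise ValueError(f"{name}: constant data, normality undefined")
        ps[name] = float(sps.shapiro(g).pvalue)
    return ps, all(p >= alpha for p in ps.values())


def compare_parametric(groups, alpha: float = 0.05, labels=None,
                       equal_var: bool = True) -> GroupComparison:
    """One-way ANOVA with Bonferroni-corrected pairwise t-tests."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    names = _labels(gs, labels)
    f_stat, p_global = sps.f_oneway(*gs)
    pairs = list(combinations(range(len(gs)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        p_raw = float(sps.ttest_ind(gs[i], gs[j], equal_var=equal_var).pvalue)
        p_adj = min(1.0, p_raw * m)
        pairwise.append((names[i], names[j], p_adj, p_adj < alpha))
    return GroupComparison("anova_bonferroni", float(f_stat), float(p_global),
                           pairwise, alpha)


def dunn_posthoc(groups, alpha: float = 0.05, labels=None):
    """Dunn's z-tests on mean ranks with Bonferroni adjustment.

    Pooled ranks with midrank ties; the z denominator carries the standard
    tie correction term Σ(t³−t)/(12(N−1)).
    """
    gs = _as_groups(groups)
    names = _labels(gs, labels)
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in gs:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(gs)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        out.append((names[i], names[j], float(p_adj), p_adj < alpha))
    return out


def compare_nonparametric(groups, alpha: float = 0.05, labels=None) -> GroupComparison:
    """Kruskal–Wallis H (tie-corrected) with Dunn's Bonferroni post-hoc."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    try:
        h_stat, p_global = sps.kruskal(*gs)
    except ValueError:  # all values identical -> H = 0, nothing to test
        h_stat, p_global = 0.0, 1.0
    pairwise = dunn_posthoc(gs, alpha, labels)
    return GroupComparison("kruskal_dunn", float(h_stat), float(p_global),
                           pairwise, alpha)


def compare_auto(groups, alpha: float = 0.05, labels=None,
                 force: str | None = None) -> GroupComparison:
    """Normality-gated comparison: ANOVA/Bonferroni iff all groups pass
    Shapiro–Wilk at alpha, Kruskal–Wallis/Dunn otherwise.

    ``force`` = "parametric" or "nonparametric" overrides the gate.
    """
    ps, parametric = normality_gate(groups, alpha, labels)
    if force == "parametric":
        parametric = True
    elif force == "nonparametric":
        parametric = False
    elif force is not None:
        raise ValueError("force must be None, 'parametric' or 'nonparametric'")
    if parametric:
        result = compare_parametric(groups, alpha, labels)
    else:
        result = compare_nonparametric(groups, alpha, labels)
    result.normality_ps = ps
    return result


def two_group_ttest(a, b, equal_var: bool = False) -> float:
    """Two-sided t-test p-value (Welch by default; Student with equal_var=True)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return 1.0 if np.isnan(p) else p
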