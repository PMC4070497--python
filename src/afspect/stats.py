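"""Group-comparison workflow for per-sample spectral metrics.

Groups are screened for normality (Shapiro-Wilk per group).  When every
group passes, the parametric route runs a one-way ANOVA with the
Student-Newman-Keuls (SNK) stepwise pairwise procedure on the studentized
range; otherwise the nonparametric route runs Kruskal-Wallis with Dunn's
pairwise test under Holm adjustment.  Significance is declared at
alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError

__all__ = ["PairwiseResult", "GroupComparison", "compare_groups"]


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    p_value: float
    significant: bool
    statistic: float = float("nan")


@dataclass
class GroupComparison:
    """Full routed comparison of one metric across conditions."""

    metric_name: str
    groups: dict
    route_taken: str  # "parametric" | "nonparametric"
    omnibus_p: float
    normality_p: dict
    pairwise: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha

    def pair(self, a: str, b: str) -> PairwiseResult:
        for pr in self.pairwise:
            if {pr.group_a, pr.group_b} == {a, b}:
                return pr
        raise KeyError((a, b))


def _shapiro_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p; degenerate (constant) samples count as non-normal.

    Two-value groups cannot be screened (the test needs n >= 3) and are
    treated as passing, since normality cannot be rejected.
    """
    if np.ptp(values) == 0:
        return 0.0
    if values.size < 3:
        return 1.0
    return float(sps.shapiro(values).pvalue)


def _snk(groups: dict, alpha: float) -> tuple:
    """One-way ANOVA + Student-Newman-Keuls stepwise pairwise procedure.

    Each pair of groups spanning ``p`` ordered means is tested against the
    studentized range distribution with ``p`` and the ANOVA error df; a
    pair is declared significant only if its own range test and the tests
    of every wider range containing it are significant (the SNK stepwise
    protection).  Unbalanced groups use the harmonic mean of the pair's
    sizes.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_error = n_total - k
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        # identical constants everywhere: nothing to compare
        pairs = [PairwiseResult(a, b, 1.0, False) for a, b in combinations(labels, 2)]
        return 1.0, pairs
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df_error
    omnibus = sps.f_oneway(*arrays)
    omnibus_p = float(omnibus.pvalue) if np.isfinite(omnibus.pvalue) else 1.0

    order = np.argsort([a.mean() for a in arrays])
    means = [arrays[i].mean() for i in order]
    sizes = [arrays[i].size for i in order]
    ordered_labels = [labels[i] for i in order]

    # own-range test per ordered pair (i < j), span = j - i + 1
    raw = {}
    for i, j in combinations(range(k), 2):
        span = j - i + 1
        n_h = 2.0 / (1.0 / sizes[i] + 1.0 / sizes[j])
        se = np.sqrt(mse / n_h)
        q = abs(means[j] - means[i]) / se if se > 0 else 0.0
        p = float(sps.studentized_range.sf(q, span, df_error)) if se > 0 else 1.0
        raw[(i, j)] = (q, p)

    pairs = []
    for i, j in combinations(range(k), 2):
        q, p_own = raw[(i, j)]
        # stepwise protection: every containing range must also reject
        containing_ps = [raw[(a, b)][1] for a in range(0, i + 1)
                         for b in range(j, k) ]
        p_eff = max(containing_ps)
        pairs.append(PairwiseResult(
            ordered_labels[i], ordered_labels[j], p_eff,
            bool(p_eff < alpha), statistic=q,
        ))
    return omnibus_p, pairs


def _dunn_holm(groups: dict, alpha: float) -> tuple:
    """Kruskal-Wallis omnibus + Dunn's pairwise z tests, Holm-adjusted."""
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        pairs = [PairwiseResult(a, b, 1.0, False) for a, b in combinations(labels, 2)]
        return 1.0, pairs
    omnibus_p = float(sps.kruskal(*arrays).pvalue)

    n = grand.size
    ranks = sps.rankdata(grand)
    # tie correction for the rank variance
    _, counts = np.unique(grand, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {}
    start = 0
    for lab, a in zip(labels, arrays):
        mean_ranks[lab] = ranks[start:start + a.size].mean()
        start += a.size
    sizes = {lab: a.size for lab, a in zip(labels, arrays)}

    raw_p, stats_, pair_labels = [], [], []
    for a, b in combinations(labels, 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var) if var > 0 else 0.0
        raw_p.append(2.0 * sps.norm.sf(abs(z)))
        stats_.append(z)
        pair_labels.append((a, b))
    reject, p_adj, *_ = multipletests(raw_p, alpha=alpha, method="holm")
    pairs = [
        PairwiseResult(a, b, float(p), bool(r), statistic=float(z))
        for (a, b), p, r, z in zip(pair_labels, p_adj, reject, stats_)
    ]
    return omnibus_p, pairs


def compare_groups(groups: dict, alpha: float = 0.05,
                   metric_name: str = "") -> GroupComparison:
    """Route one metric's per-condition values through the comparison workflow.

    Parameters
    ----------
    groups
        Mapping condition label -> array of per-sample values (>= 2 groups,
        each with >= 2 values).
    alpha
        Significance level for the normality screen, the omnibus test and
        the pairwise procedures.

    Returns
    -------
    GroupComparison
        Route taken, omnibus p, and a pairwise result for every unordered
        pair of conditions.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    clean = {}
    for lab, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise InsufficientDataError(f"group {lab!r} has fewer than two values")
        clean[lab] = arr

    normality_p = {lab: _shapiro_p(a) for lab, a in clean.items()}
    parametric = all(p >= alpha for p in normality_p.values())
    if parametric:
        omnibus_p, pairs = _snk(clean, alpha)
        route = "parametric"
    else:
        omnibus_p, pairs = _dunn_holm(clean, alpha)
        route = "nonparametric"
    return GroupComparison(
        metric_name=metric_name, groups=clean, route_taken=route,
        omnibus_p=omnibus_p, normality_p=normality_p, pairwise=pairs,
        alpha=alpha,
    )
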