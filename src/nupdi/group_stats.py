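"""Nonparametric group statistics.

The statistical battery used throughout the imaging quantification:
Dunn's multiple-comparison test of every group against a reference
(following a Kruskal–Wallis design), the Wilcoxon signed-rank test for
paired comparisons, the Wilcoxon rank-sum test for two independent
samples, and star-annotation helpers.

Dunn's z for group g versus the reference uses pooled mid-ranks with the
standard tie correction:

    z = (Rbar_g - Rbar_ref) / sqrt( (N(N+1)/12 - T) * (1/n_g + 1/n_ref) )

with T = sum(t^3 - t) / (12 (N - 1)) over tie groups of size t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "dunn_vs_reference",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "significance_stars",
]

_ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}
EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 10


@dataclass
class GroupComparison:
    """One family of reference comparisons from Dunn's test."""

    table: pd.DataFrame  # comparison, n_group, n_ref, z, p, p_adjusted, stars
    reference: str
    adjust_method: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def significance_stars(p: float) -> str:
    """Figure-legend star convention: thresholds 0.05/0.01/0.001/0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


def _pooled_midranks(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-ranks of the pooled sample and the Dunn tie term T."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    ties = counts[counts > 1]
    t_term = float((ties**3 - ties).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    return ranks, t_term


def dunn_vs_reference(
    groups: dict[str, np.ndarray],
    reference: str,
    adjust: str = "holm",
) -> GroupComparison:
    """Dunn's multiple-comparison test of each group against a reference.

    Two-sided p-values from the normal distribution of z, adjusted across
    the family of comparisons (Holm by default; "bonferroni" and "bh"
    selectable).
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjust!r}; "
                         f"choose from {sorted(_ADJUST_METHODS)}")
    labels, samples = [], []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 1:
            raise ValueError(f"group {name!r} is empty")
        labels.extend([name] * len(vals))
        samples.append(vals)
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical: no variance to rank")
    labels = np.asarray(labels)
    ranks, t_term = _pooled_midranks(pooled)
    n_total = len(pooled)
    var_unit = n_total * (n_total + 1) / 12.0 - t_term
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    n_per = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for g in groups:
        if g == reference:
            continue
        se = np.sqrt(var_unit * (1.0 / n_per[g] + 1.0 / n_per[reference]))
        z = (mean_rank[g] - mean_rank[reference]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(dict(comparison=f"{g} vs {reference}",
                         n_group=n_per[g], n_ref=n_per[reference],
                         z=z, p=min(p, 1.0)))
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(
        table["p"].to_numpy(), method=_ADJUST_METHODS[adjust])[1]
    table["stars"] = table["p_adjusted"].map(significance_stars)
    return GroupComparison(table=table, reference=reference, adjust_method=adjust)


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H and p across the groups (omnibus companion)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*[np.asarray(v, dtype=float) for v in groups.values()])
    return float(h), float(p)


def wilcoxon_signed_rank(
    before: np.ndarray,
    after: np.ndarray,
    zero_method: str = "wilcox",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples; returns (W, p).

    Zero differences are dropped by default (Wilcoxon's convention;
    "pratt" selectable).  The null distribution is exact for n <= 25
    retained pairs and a continuity-corrected normal approximation above.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    diffs = after - before
    n_nonzero = int((diffs != 0).sum())
    if n_nonzero == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if n_nonzero <= EXACT_SIGNED_RANK_MAX_N else "approx"
    # ties among nonzero |differences| force the approximation
    if method == "exact":
        nz = np.abs(diffs[diffs != 0])
        if len(np.unique(nz)) < len(nz):
            method = "approx"
    res = stats.wilcoxon(after, before, zero_method=zero_method,
                         alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) test; returns (U, p).

    Exact null distribution when both samples have <= 10 observations and
    no cross-sample ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = (len(a) <= EXACT_RANK_SUM_MAX_N and len(b) <= EXACT_RANK_SUM_MAX_N
             and not has_ties)
    res = stats.mannwhitneyu(
        a, b, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return float(res.statistic), float(res.pvalue)
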