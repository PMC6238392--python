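"""Statistical tests used across the analysis.

Rank-sum comparison of m6A/A distributions (Mann-Whitney U), hypergeometric
overlap tests for gene-set intersections, Pearson correlation for replicate
concordance, and exact Venn region counting for up to three sets. The
numerics are delegated to scipy.stats; this module fixes the conventions
(sidedness, tie handling, tail definition) used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "hypergeometric_tail",
    "pearson_r",
    "overlap_counts",
]

#: Exact Mann-Whitney enumeration is used up to this pooled sample size.
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sizes: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U rank-sum test with midrank tie handling.

    The p-value is exact (full enumeration) when the pooled sample size is at
    most 12 and no ties are present; otherwise the normal approximation with
    tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample in Mann-Whitney test")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and pooled.size <= EXACT_MW_MAX_N
    res = _stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney-exact" if exact else "mann-whitney-normal",
        sizes={"n1": int(x.size), "n2": int(y.size)},
    )


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> TestResult:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes in a draw of ``n`` from a universe of ``N`` containing
    ``K`` marked elements; the standard overlap-significance tail for two
    gene sets of sizes K and n sharing k members.
    """
    if not (0 <= k <= min(K, n) <= max(K, n) <= N):
        raise ValueError(
            f"inconsistent hypergeometric sizes k={k}, K={K}, n={n}, N={N}"
        )
    # survival function evaluated stably by scipy (log-space internally)
    p = float(_stats.hypergeom.sf(k - 1, N, K, n))
    return TestResult(
        statistic=float(k),
        p_value=min(max(p, 0.0), 1.0),
        method="hypergeometric-upper-tail",
        sizes={"k": k, "K": K, "n": n, "N": N},
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation; r as the statistic, r^2 in extras."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("Pearson correlation needs two samples of equal size >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance sample in Pearson correlation")
    res = _stats.pearsonr(x, y)
    r = float(res.statistic)
    return TestResult(
        statistic=r,
        p_value=float(res.pvalue),
        method="pearson",
        sizes={"n": int(x.size)},
        extras={"r_squared": r * r},
    )


def overlap_counts(sets: Mapping[str, Iterable]) -> dict[frozenset, int]:
    """Exact Venn region counts for up to three named sets.

    Returns a mapping from the frozenset of set names containing a region's
    elements exclusively to the region's count; counts sum to |union|.
    """
    if len(sets) > 3:
        raise ValueError("overlap_counts supports at most 3 sets")
    named = {name: set(members) for name, members in sets.items()}
    universe = set().union(*named.values()) if named else set()
    regions: dict[frozenset, int] = {}
    for element in universe:
        membership = frozenset(n for n, s in named.items() if element in s)
        regions[membership] = regions.get(membership, 0) + 1
    return regions
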