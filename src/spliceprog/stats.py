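"""Shared statistics: set-overlap tests, BH FDR, Mann-Whitney U.

Thin, validated wrappers around scipy/statsmodels with the conventions
used throughout the package fixed in one place (upper-tail hypergeometric
for enrichment, R-style two-sided Fisher, exact Mann-Whitney for small
samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["OverlapTestResult", "overlap_test", "bh_fdr", "mann_whitney_u"]


@dataclass(frozen=True)
class OverlapTestResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    method: str
    p_value: float
    odds_ratio: float | None = None


def overlap_test(set_a, set_b, universe, method: str = "hypergeometric") -> OverlapTestResult:
    """Test whether two gene/event sets overlap more than chance.

    ``hypergeometric`` gives the upper-tail P(X >= |A∩B|) of drawing |B|
    elements from a universe containing |A| successes; ``fisher`` gives the
    two-sided Fisher exact p on the 2x2 table, plus the sample odds ratio.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe:
        raise ValueError("set A not contained in universe")
    if not set_b <= universe:
        raise ValueError("set B not contained in universe")
    N, a, b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    if method == "hypergeometric":
        p = float(sps.hypergeom.sf(k - 1, N, a, b))
        return OverlapTestResult(a, b, k, N, method, min(p, 1.0))
    if method == "fisher":
        table = [[k, a - k], [b - k, N - a - b + k]]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return OverlapTestResult(a, b, k, N, method, float(p), float(odds))
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with exact small-sample p and tie-corrected normal otherwise.

    The exact null distribution is used whenever n+m <= 16 and there are no
    ties across the pooled sample; larger or tied samples fall back to the
    tie-corrected normal approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 16 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
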