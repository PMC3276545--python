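"""Rank and count statistics used throughout the screen analysis.

Two tests recur in the analysis: the Mann-Whitney-Wilcoxon rank-sum test for
comparing effect-size distributions between mutant classes, and Fisher's exact
test for comparing colony-formation counts. Both are implemented exactly for
small samples (the regime in which the screen's class sizes often sit) and by
approximation for large ones.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["mww_test", "fisher_exact_test", "rankdata_u"]

#: pooled sample size at or below which the MWW p-value is computed by
#: complete enumeration of group assignments
EXACT_ENUMERATION_LIMIT = 12


def rankdata_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U statistic for sample ``x`` (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def _exact_mww_p(x: np.ndarray, y: np.ndarray, sided: str) -> float:
    """Permutation-exact MWW p by enumerating all group assignments.

    Under label permutation the U distribution is symmetric about
    n1*n2/2 even in the presence of ties, so the two-sided p-value is the
    probability of a U at least as far from n1*n2/2 as observed.
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    center = n1 * n2 / 2.0
    n_total = n1 + n2
    hits = 0
    total = comb(n_total, n1)
    for idx in combinations(range(n_total), n1):
        u = ranks[list(idx)].sum() - offset
        if sided == "two-sided":
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                hits += 1
        elif sided == "greater":
            if u >= u_obs - 1e-12:
                hits += 1
        else:  # less
            if u <= u_obs + 1e-12:
                hits += 1
    return hits / total


def _approx_mww_p(x: np.ndarray, y: np.ndarray, sided: str) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = x.size, y.size
    n = n1 + n2
    u = rankdata_u(x, y)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all values tied: no evidence of a shift
    sd = np.sqrt(var)
    if sided == "two-sided":
        z = (abs(u - mu) - 0.5) / sd
        return float(2 * sps.norm.sf(max(z, 0.0)))
    if sided == "greater":
        z = (u - mu - 0.5) / sd
    else:
        z = -(u - mu + 0.5) / sd
    return float(sps.norm.sf(z))


def mww_test(x, y, sided: str = "two-sided") -> float:
    """Mann-Whitney-Wilcoxon rank-sum p-value.

    Exact by enumeration when the pooled sample size is at most
    ``EXACT_ENUMERATION_LIMIT``; otherwise a tie-corrected normal
    approximation with continuity correction.

    Parameters
    ----------
    x, y
        The two samples (e.g. |Z| effect sizes of two mutant classes).
    sided
        ``"two-sided"``, ``"greater"`` (x tends larger), or ``"less"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if sided not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown sidedness {sided!r}")
    if x.size + y.size <= EXACT_ENUMERATION_LIMIT:
        return min(1.0, _exact_mww_p(x, y, sided))
    return min(1.0, _approx_mww_p(x, y, sided))


def fisher_exact_test(a_success: int, a_total: int,
                      b_success: int, b_total: int) -> float:
    """Two-sided Fisher exact p-value for two success/total pairs.

    The 2x2 table is [[a_success, a_total-a_success],
    [b_success, b_total-b_success]]; the two-sided p sums hypergeometric
    point probabilities no larger than that of the observed table (the
    point-probability rule, as used for colony-formation comparisons).
    """
    for v in (a_success, a_total, b_success, b_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a_total == 0 or b_total == 0:
        raise ValueError("group totals must be positive")
    if a_success > a_total or b_success > b_total:
        raise ValueError("successes exceed totals")
    n = a_total + b_total
    k = a_success + b_success  # total successes; margin fixed
    dist = sps.hypergeom(n, k, a_total)
    support = np.arange(max(0, k - b_total), min(k, a_total) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a_success)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))
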