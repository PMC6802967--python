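"""Comparative statistics for protein half-life groups.

Two questions are asked downstream of half-life estimation: do protein
classes (e.g. INM vs NET vs ER membrane residents) differ in half-life,
and does the extraluminal domain size of INM proteins correlate with their
half-life. The first is answered with a Mann-Whitney rank-sum test, the
second with rank (Spearman, primary — half-lives are heavy-tailed) and
linear (Pearson) correlation.

The Mann-Whitney U statistic is computed with midranks for ties. For small
groups the two-sided p-value is exact: the U distribution is obtained by
full enumeration of all C(n_a+n_b, n_a) group assignments of the observed
(tied) values, and the one-sided tail probability is doubled, capped at 1.
Larger groups fall back to the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats

from .errors import DomainError

#: Largest number of enumerated arrangements for which the exact Mann-Whitney
#: null distribution is computed.
DEFAULT_ENUMERATION_CAP = 10_000

#: Largest n for which the Spearman permutation p-value is exact.
SPEARMAN_EXACT_MAX_N = 10


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of two half-life groups."""

    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    U_statistic: float
    p_two_sided: float
    method: str  # "exact" or "normal-approximation"


@dataclass(frozen=True)
class CorrelationResult:
    """Paired rank and linear correlation with two-sided p-values.

    Coefficients are None (with ``note`` set) when an input vector is
    constant, where correlation is undefined.
    """

    n: int
    spearman_rho: float | None
    p_spearman: float | None
    pearson_r: float | None
    p_pearson: float | None
    note: str | None = None


def _u_statistic(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """U for group A via midranks: U_a = R_a - n_a(n_a+1)/2."""
    n_a = len(values_a)
    ranks = stats.rankdata(np.concatenate([values_a, values_b]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)


def _exact_p(pooled: np.ndarray, n_a: int, observed_u: float) -> float:
    """Two-sided exact p by enumerating every assignment of group labels."""
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n_a)]
    )
    total = len(us)
    mean_u = n_a * (n - n_a) / 2
    if observed_u <= mean_u:
        tail = int(np.sum(us <= observed_u + 1e-9))
    else:
        tail = int(np.sum(us >= observed_u - 1e-9))
    return min(1.0, 2.0 * tail / total)


def _normal_p(pooled: np.ndarray, n_a: int, n_b: int, observed_u: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma_sq = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0:  # all values tied: no evidence either way
        return 1.0
    mean_u = n_a * n_b / 2.0
    shift = observed_u - mean_u
    # continuity correction toward the mean
    z = (shift - math.copysign(0.5, shift)) / math.sqrt(sigma_sq) if shift else 0.0
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def mann_whitney(
    values_a,
    values_b,
    group_a_label: str = "A",
    group_b_label: str = "B",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> GroupComparison:
    """Mann-Whitney rank-sum comparison with exact small-sample p-values.

    The exact method is used whenever the number of label arrangements
    C(n_a+n_b, n_a) does not exceed ``enumeration_cap``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("mann_whitney requires two non-empty groups")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise DomainError("mann_whitney requires finite values")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if math.comb(a.size + b.size, a.size) <= enumeration_cap:
        p = _exact_p(pooled, a.size, u)
        method = "exact"
    else:
        p = _normal_p(pooled, a.size, b.size, u)
        method = "normal-approximation"
    return GroupComparison(
        group_a_label=group_a_label,
        group_b_label=group_b_label,
        n_a=int(a.size),
        n_b=int(b.size),
        U_statistic=u,
        p_two_sided=float(p),
        method=method,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, observed_rho: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (|rho| >= |observed|).

    Permuting y permutes the same rank multiset, so the rank means and the
    normalising denominator are permutation-invariant and rho reduces to a
    dot product of centred ranks; the n! permutations are evaluated as
    chunked matrix products.
    """
    rx_c = stats.rankdata(x) - (len(x) + 1) / 2
    ry_c = stats.rankdata(y) - (len(y) + 1) / 2
    denom = float(np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2)))
    threshold = abs(observed_rho) - 1e-12
    count = 0
    total = 0
    chunk: list[tuple[float, ...]] = []
    chunk_size = 100_000
    for perm in permutations(ry_c):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            rhos = np.asarray(chunk) @ rx_c / denom
            count += int(np.sum(np.abs(rhos) >= threshold))
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = np.asarray(chunk) @ rx_c / denom
        count += int(np.sum(np.abs(rhos) >= threshold))
        total += len(chunk)
    return count / total


def size_halflife_correlation(sizes, half_lives) -> CorrelationResult:
    """Correlate extraluminal domain size with half-life.

    Spearman's rho (exact permutation p for n <= 10, t-approximation
    above) and Pearson's r with its usual t-based p. Constant inputs make
    both coefficients undefined; they are reported as None with a note.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(half_lives, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("sizes and half_lives must be equal-length 1-D lists")
    if x.size < 3:
        raise DomainError("correlation requires at least 3 pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise DomainError("correlation requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        which = "sizes" if np.ptp(x) == 0 else "half_lives"
        return CorrelationResult(
            n=int(x.size),
            spearman_rho=None, p_spearman=None,
            pearson_r=None, p_pearson=None,
            note=f"correlation undefined: {which} vector is constant",
        )
    spearman = stats.spearmanr(x, y)
    rho = float(spearman.statistic)
    if x.size <= SPEARMAN_EXACT_MAX_N:
        p_s = _spearman_exact_p(x, y, rho)
    else:
        p_s = float(spearman.pvalue)
    pearson = stats.pearsonr(x, y)
    return CorrelationResult(
        n=int(x.size),
        spearman_rho=rho,
        p_spearman=float(p_s),
        pearson_r=float(pearson.statistic),
        p_pearson=float(pearson.pvalue),
    )
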