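"""Chromosome-contrast statistics: chi-square on gene counts, Mann-Whitney on RPKM.

Both cores are implemented from first principles so they can be verified
against brute-force oracles: the 2x2 Pearson chi-square is the explicit
sum of (O - E)^2 / E over the four cells (no continuity correction by
default), and the Mann-Whitney U test uses midranks with an exact null
distribution (subset-sum recursion over rank sums) for small tie-free
samples and a tie-corrected, continuity-corrected normal approximation
otherwise.  Only the chi-square and normal tail areas come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

EXACT_MAX_PRODUCT = 400  # exact Mann-Whitney when n_a * n_b <= this and no ties


@dataclass(frozen=True)
class ProportionTest:
    group_a: tuple[str, int, int]  # label, successes, total
    group_b: tuple[str, int, int]
    chi2: float
    df: int
    p_value: float
    low_expected: bool  # some expected cell < 1


@dataclass(frozen=True)
class RankTest:
    group_a: tuple[str, int]  # label, n
    group_b: tuple[str, int]
    u_statistic: float
    p_value: float
    method: str  # exact | normal_approx


def chi_square_2x2(
    successes_a: int,
    total_a: int,
    successes_b: int,
    total_b: int,
    label_a: str = "a",
    label_b: str = "b",
    yates: bool = False,
) -> ProportionTest:
    """Pearson chi-square on the 2x2 success/failure table of two groups."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= successes_a <= total_a and 0 <= successes_b <= total_b):
        raise ValueError("successes must lie in [0, total]")
    obs = np.array(
        [[successes_a, total_a - successes_a], [successes_b, total_b - successes_b]],
        dtype=float,
    )
    grand = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, diff**2 / expected, 0.0)
    stat = float(cells.sum())
    p = float(chi2_dist.sf(stat, 1))
    return ProportionTest(
        group_a=(label_a, int(successes_a), int(total_a)),
        group_b=(label_b, int(successes_b), int(total_b)),
        chi2=stat,
        df=1,
        p_value=p,
        low_expected=bool((expected < 1).any()),
    )


def _exact_u_cdf(n_a: int, n_b: int, u: float) -> float:
    """P(U_a <= u) under the tie-free null, by subset-sum counting.

    Counts, for every k-subset of ranks {1..n_a+n_b} with k = n_a, the
    number achieving each rank sum; U_a = ranksum - n_a(n_a+1)/2.
    """
    n = n_a + n_b
    max_sum = n * (n + 1) // 2
    # ways[k][s]: k-subsets of processed ranks with sum s
    ways = np.zeros((n_a + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_a), 0, -1):
            ways[k, rank:] += ways[k - 1, : max_sum + 1 - rank]
    offset = n_a * (n_a + 1) // 2
    u_cut = int(np.floor(u)) + offset
    total = ways[n_a].sum()
    return float(ways[n_a, : u_cut + 1].sum() / total)


def mann_whitney(values_a, values_b, method: str = "auto", label_a: str = "a", label_b: str = "b") -> RankTest:
    """Two-sided Mann-Whitney U test with midranks.

    method ``auto`` uses the exact subset-enumeration null when
    n_a * n_b <= 400 and there are no ties, falling back to the normal
    approximation with tie-corrected variance and continuity correction;
    ``exact`` and ``normal_approx`` force the respective path.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a

    has_ties = np.unique(pooled).size < pooled.size
    if method == "exact" and has_ties:
        raise ValueError("exact method is undefined with ties; use normal_approx")
    use_exact = method == "exact" or (
        method == "auto" and not has_ties and n_a * n_b <= EXACT_MAX_PRODUCT
    )
    if use_exact:
        p = min(1.0, 2.0 * _exact_u_cdf(n_a, n_b, min(u_a, u_b)))
        used = "exact"
    else:
        n = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum())
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_a - n_a * n_b / 2.0) - 0.5) / np.sqrt(var)
            p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
        used = "normal_approx"
    return RankTest(
        group_a=(label_a, n_a),
        group_b=(label_b, n_b),
        u_statistic=float(u_a),
        p_value=p,
        method=used,
    )


def significance_stars(p: float) -> str:
    """Conventional star coding: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def proportion_pct(count: int, total: int) -> float:
    """Percentage 100*count/total, the unit used throughout the reports."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (opt-in report extra; raw p-values remain primary)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
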