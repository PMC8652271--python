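"""Rank and circular significance tests used by the analysis pipeline.

Two tests only: the two-sided Mann–Whitney U test for comparing two
independent samples (e.g. nuclear migration distances in flat vs curved
regions, or replicate curvature summaries between virtual-experiment arms)
and the Rayleigh test of circular uniformity for division-orientation
angles.

The U statistic and the normal-approximation branch (midranks, tie
correction, continuity correction) come from scipy; the exact two-sided
p-value is computed from the tie-free null distribution of U, built by
dynamic programming, as p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). The exact
branch is used when the enumeration is feasible (C(n_a+n_b, n_a) ≤ 2×10⁵)
and there are no ties.

The Rayleigh p-value uses the Greenwood–Durand series approximation
p = e^{−z}[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)], z = nR̄²,
clipped to [0, 1]; axial data (e.g. division axes) are angle-doubled first.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "mann_whitney_u", "rayleigh_test"]

EXACT_ENUMERATION_LIMIT = 200_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # {"exact", "normal_approx", "greenwood_durand", "monte_carlo"}
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _u_null_counts(n_a: int, n_b: int) -> np.ndarray:
    """counts[u] = number of orderings with U = u under the tie-free null,
    by the standard recurrence over which group contributes the next-largest
    value."""
    # c_{i,j}(u) = c_{i-1,j}(u-j) + c_{i,j-1}(u): the largest pooled value is
    # either an a (contributing j to U) or a b
    u_max = n_a * n_b
    dp = np.zeros((n_b + 1, u_max + 1))
    dp[:, 0] = 1.0  # zero a-observations: U = 0
    for _ in range(n_a):
        new = np.zeros_like(dp)
        new[0, 0] = 1.0
        for j in range(1, n_b + 1):
            new[j, j:] = dp[j, : u_max + 1 - j]
            new[j, :] += new[j - 1, :]
        dp = new
    return dp[n_b]


def _exact_two_sided_p(u: float, n_a: int, n_b: int) -> float:
    counts = _u_null_counts(n_a, n_b)
    total = counts.sum()
    k = int(round(u))
    p_le = counts[: k + 1].sum() / total
    p_ge = counts[k:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Returns the U statistic of ``group_a`` (ties as midranks). The p-value is
    exact (null-distribution enumeration) when there are no ties and
    C(n_a+n_b, n_a) ≤ 2×10⁵, otherwise a normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    feasible = comb(a.size + b.size, a.size) <= EXACT_ENUMERATION_LIMIT
    if feasible and not has_ties:
        p = _exact_two_sided_p(u, a.size, b.size)
        method = "exact"
    else:
        p = float(res.pvalue)
        method = "normal_approx"
    return TestResult(statistic=u, p_value=min(p, 1.0), method=method, n=(a.size, b.size))


def rayleigh_test(angles_deg, axial: bool = False) -> TestResult:
    """Rayleigh test of circular uniformity (Greenwood–Durand p-value).

    ``angles_deg`` are angles in degrees; with ``axial=True`` they are
    doubled first, the standard correction for axial (undirected) data such
    as division axes. The statistic reported is z = n·R̄².
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 3:
        raise ValueError("Rayleigh test needs at least 3 angles")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    theta = np.radians(angles * (2.0 if axial else 1.0))
    n = angles.size
    rbar = float(np.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / n)
    z = n * rbar**2
    correction = (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(np.clip(np.exp(-z) * correction, 0.0, 1.0))
    return TestResult(statistic=z, p_value=p, method="greenwood_durand", n=(n,))
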