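"""Prospective power analysis for G2-based multinomial parameter tests.

The effect size is Cohen's w for chi-square-family tests,

    w = sqrt( sum_i (p1_i - p0_i)^2 / p0_i ),

and the test statistic under the alternative is approximately noncentral
chi-square with noncentrality lambda = N * w**2, where N is the total
number of observations entering the multinomial analysis (here:
participants x test items, since responses are pooled over participants).
Power is the survival probability of that distribution at the central
chi-square critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerQuery",
    "PowerResult",
    "effect_size_w",
    "power_chisq",
    "min_detectable_w",
]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of a noncentral chi-square power computation."""

    w: float
    N: float
    df: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("effect size w must be nonnegative")
        if self.N <= 0:
            raise ValueError("observation count N must be positive")
        if self.df <= 0:
            raise ValueError("df must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def noncentrality(self) -> float:
        return self.N * self.w**2


@dataclass(frozen=True)
class PowerResult:
    """Computed power, with the noncentrality and critical value used."""

    power: float
    noncentrality: float
    critical_value: float

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "noncentrality": self.noncentrality,
            "critical_value": self.critical_value,
        }


def effect_size_w(p_null, p_alt) -> float:
    """Cohen's w between two category distributions.

    Both distributions must sum to one; ``p_null`` must be strictly
    positive (a zero null cell makes w undefined).
    """
    p0 = np.asarray(p_null, dtype=float)
    p1 = np.asarray(p_alt, dtype=float)
    if p0.shape != p1.shape:
        raise ValueError("distributions must have the same number of categories")
    for name, p in (("p_null", p0), ("p_alt", p1)):
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} is not a probability distribution")
    if np.any(p0 <= 0):
        raise ValueError("p_null has a zero cell; w is undefined")
    return float(np.sqrt(np.sum((p1 - p0) ** 2 / p0)))


def power_chisq(query: PowerQuery) -> PowerResult:
    """Power of the chi-square test at the query's effect size and design.

    ``power = P(X > crit)`` with ``X ~ noncentral chi2(df, N * w**2)`` and
    ``crit`` the central chi-square (1 - alpha) quantile.  At w = 0 the
    distribution is central and the power equals alpha.
    """
    crit = float(stats.chi2.ppf(1.0 - query.alpha, query.df))
    lam = query.noncentrality
    if lam == 0.0:
        power = float(stats.chi2.sf(crit, query.df))
    else:
        power = float(stats.ncx2.sf(crit, query.df, lam))
    return PowerResult(power=power, noncentrality=lam, critical_value=crit)


def min_detectable_w(
    power_target: float,
    N: float,
    df: int,
    alpha: float = 0.05,
    tol: float = 1e-6,
) -> float:
    """Smallest effect size w reaching ``power_target``, by bisection.

    Power is strictly increasing in w (for w > 0), so bisection on
    [0, w_hi] converges; ``w_hi`` is grown until it brackets the target.
    """
    if not alpha < power_target < 1.0:
        raise ValueError("power_target must lie in (alpha, 1)")

    def pw(w: float) -> float:
        return power_chisq(PowerQuery(w=w, N=N, df=df, alpha=alpha)).power

    lo, hi = 0.0, 0.1
    while pw(hi) < power_target:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("failed to bracket the target power")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pw(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi
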