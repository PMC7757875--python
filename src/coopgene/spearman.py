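"""Spearman rank correlation with exact permutation p-values at small n.

The strategy classifier tests segments of a 21-entry contingent schedule,
some as short as three points.  At those lengths the usual t-approximation
to the null distribution of Spearman's rho is unreliable, so for n <= 8
the p-value is computed exactly by enumerating all n! orderings of one
variable's ranks (ties handled by midranks, which makes the enumeration a
permutation test rather than the tie-free classical table).  For n > 8 the
two-sided p comes from the t-approximation t = rho*sqrt((n-2)/(1-rho^2))
with n-2 degrees of freedom, except that |rho| = 1 is reported as p = 0.

The permutation null distribution of rho depends only on the two rank
*multisets*, not on the observed pairing, so the sorted distribution is
cached per multiset pair; tie-free segments of equal length all share a
single cached distribution, which makes repeated classification cheap.

A segment with zero rank variance on either side has no defined
correlation; such calls return an *undefined* result that downstream logic
treats as not significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import special

EXACT_N_MAX = 8
_TOL = 1e-12

__all__ = ["SpearmanResult", "spearman_with_p", "EXACT_N_MAX"]


@dataclass(frozen=True)
class SpearmanResult:
    """rho and p, plus whether the correlation is defined and how p was got."""

    rho: float
    p: float
    defined: bool = True
    exact: bool = False

    def significant(self, alpha: float, sign: int) -> bool:
        """True when rho is defined, has the required sign (+1/-1), and the
        stored p (two-sided or directional, per how it was computed) is
        below alpha."""
        if not self.defined:
            return False
        if sign > 0 and self.rho <= 0:
            return False
        if sign < 0 and self.rho >= 0:
            return False
        return self.p < alpha


@lru_cache(maxsize=None)
def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1 as an (n!, n) int array."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


@lru_cache(maxsize=256)
def _null_distributions(
    xr_sorted: tuple, yr_sorted: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """(sorted signed rho, sorted |rho|) over all n! pairings of the two
    rank multisets.  Invariant to the observed ordering of either side."""
    xr = np.asarray(xr_sorted, dtype=float)
    yr = np.asarray(yr_sorted, dtype=float)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    perms = _perm_matrix(xr.size)
    rho_all = (yc[perms] @ xc) / denom
    return np.sort(rho_all), np.sort(np.abs(rho_all))


def _midranks(a: np.ndarray) -> np.ndarray:
    """Average (mid) ranks, 1-based; ties share their mean rank."""
    if a.size > 1 and (a[1:] > a[:-1]).all():  # strictly increasing: no ties
        return np.arange(1.0, a.size + 1.0)
    _, inverse, counts = np.unique(a, return_inverse=True, return_counts=True)
    ends = np.cumsum(counts)
    starts = ends - counts
    return (starts + (counts + 1) / 2.0)[inverse]


def _rank_corr(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    return float(xc @ yc / np.sqrt((xc**2).sum() * (yc**2).sum()))


def spearman_with_p(x, y, alternative: str = "two-sided") -> SpearmanResult:
    """Spearman rho with a p-value that is exact for n <= 8.

    Parameters
    ----------
    x, y : sequences of equal length n >= 2.
    alternative : "two-sided", "greater" (rho > 0), or "less" (rho < 0).

    Returns an undefined result (rho, p = nan) when either input is
    constant, since ranks then carry no variance.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"x and y must be 1-d sequences of equal length, got {x.shape} vs {y.shape}"
        )
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=float("nan"), p=float("nan"), defined=False)

    xr = _midranks(x)
    yr = _midranks(y)
    rho = _rank_corr(xr, yr)

    if n <= EXACT_N_MAX:
        signed, absed = _null_distributions(
            tuple(np.sort(xr)), tuple(np.sort(yr))
        )
        m = signed.size
        if alternative == "two-sided":
            p = (m - np.searchsorted(absed, abs(rho) - _TOL, side="left")) / m
        elif alternative == "greater":
            p = (m - np.searchsorted(signed, rho - _TOL, side="left")) / m
        else:
            p = np.searchsorted(signed, rho + _TOL, side="right") / m
        return SpearmanResult(rho=rho, p=float(p), exact=True)

    if abs(rho) >= 1.0 - _TOL:
        # perfect monotone agreement cannot arise by chance in the t-model
        rho = 1.0 if rho > 0 else -1.0
        if alternative == "two-sided":
            p = 0.0
        elif alternative == "greater":
            p = 0.0 if rho > 0 else 1.0
        else:
            p = 0.0 if rho < 0 else 1.0
        return SpearmanResult(rho=rho, p=p)

    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    # stdtr is the Student-t CDF as a bare special function (low overhead)
    if alternative == "two-sided":
        p = 2.0 * special.stdtr(n - 2, -abs(t))
    elif alternative == "greater":
        p = special.stdtr(n - 2, -t)
    else:
        p = special.stdtr(n - 2, t)
    return SpearmanResult(rho=rho, p=float(min(p, 1.0)))
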