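"""Head-to-head statistical comparison of decoy-generation algorithms.

Two algorithms are compared target by target on a performance metric; each
target is a success for an algorithm when its value is strictly better or
tied (a tie credits both sides). The resulting 2x2 win/loss table feeds
Fisher's conditional exact test and Barnard's unconditional exact test, the
standard pair for small contingency tables:

* Fisher one-sided: hypergeometric upper tail P(X >= a) with all margins
  fixed, computed with exact integer arithmetic.
* Fisher/Barnard two-sided: the doubling convention min(1, 2 * one-sided).
* Barnard one-sided: the pooled-Wald (score) variant. The nuisance success
  probability pi common to both rows is eliminated by maximization: the
  p-value is the supremum over pi in (0, 1) of the probability, under
  independent binomial sampling of both rows, of a Wald statistic at least
  as extreme as observed (ties included; tables with zero pooled variance
  count as statistic 0). The supremum is taken over a fixed grid of step
  1e-4 with bounded local refinement; for degenerate all-tied tables the
  supremum is a boundary phenomenon (it tends to 1 as pi -> 0), so the grid
  edge sets the last decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from .errors import InputError

#: Nuisance-parameter grid resolution for Barnard's test.
DEFAULT_GRID = 1e-4


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 win/loss counts: (a, b) successes/failures of algorithm 1,
    (c, d) of algorithm 2. Rows must refer to the same set of targets."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name, v in zip("abcd", self.as_tuple()):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"count {name} must be a non-negative "
                                 f"integer, got {v!r}")
        if self.a + self.b != self.c + self.d:
            raise InputError(
                f"row sums differ ({self.a + self.b} vs {self.c + self.d}); "
                f"both algorithms must be scored on the same targets")

    def as_tuple(self):
        return (self.a, self.b, self.c, self.d)

    @property
    def n_targets(self) -> int:
        return self.a + self.b

    def mirrored(self) -> "ContingencyTable":
        """Swap the two algorithms."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


def _coerce(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    arr = np.asarray(table)
    if arr.shape == (2, 2):
        return ContingencyTable(int(arr[0, 0]), int(arr[0, 1]),
                                int(arr[1, 0]), int(arr[1, 1]))
    if arr.shape == (4,):
        return ContingencyTable(*(int(v) for v in arr))
    raise InputError(f"expected a 2x2 table, got shape {arr.shape}")


def head_to_head(values1, values2, better="lower") -> ContingencyTable:
    """Per-target win/loss table for two paired result lists.

    A target is a success for an algorithm iff its value is strictly better
    than, or equal to, the other's ("better" is 'lower' or 'higher'); a tie
    therefore awards a success to both sides.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise InputError(
            f"paired value lists must be 1-D and equal length; "
            f"got {v1.shape} vs {v2.shape}")
    if better not in ("lower", "higher"):
        raise InputError(f"better must be 'lower' or 'higher', got {better!r}")
    if better == "higher":
        v1, v2 = -v1, -v2
    n = len(v1)
    a = int(np.sum(v1 <= v2))
    c = int(np.sum(v2 <= v1))
    return ContingencyTable(a, n - a, c, n - c)


def fisher_one_sided(table) -> float:
    """Upper-tail Fisher p: P(X >= a) under the hypergeometric law with all
    margins fixed (tests that algorithm 1's success rate exceeds algorithm
    2's). Exact integer arithmetic; error below 1e-12."""
    t = _coerce(table)
    n1, n2 = t.a + t.b, t.c + t.d
    k = t.a + t.c  # first-column margin
    hi = min(n1, k)
    num = sum(comb(n1, x) * comb(n2, k - x)
              for x in range(t.a, hi + 1) if 0 <= k - x <= n2)
    den = comb(n1 + n2, k)
    return num / den


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by the doubling convention: min(1, 2 * one-sided)."""
    return min(1.0, 2.0 * fisher_one_sided(table))


def _wald_matrix(n1: int, n2: int) -> np.ndarray:
    """Pooled-Wald statistic for every outcome (x1, x2); zero-variance
    outcomes (all successes or all failures) get statistic 0."""
    x1 = np.arange(n1 + 1, dtype=float)[:, None]
    x2 = np.arange(n2 + 1, dtype=float)[None, :]
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p1 - p2) / np.sqrt(var)
    return np.where(var <= 0, 0.0, t)


def barnard_one_sided(table, grid=DEFAULT_GRID) -> float:
    """Barnard's unconditional one-sided p-value (pooled-Wald variant).

    p = sup over pi of P(T >= T_obs) with X1 ~ Bin(n1, pi) and
    X2 ~ Bin(n2, pi) independent. The supremum is evaluated on a pi grid of
    the given resolution plus a bounded golden-section refinement around
    the best grid point.
    """
    if not 0 < grid < 0.5:
        raise InputError(f"grid resolution must be in (0, 0.5), got {grid}")
    t = _coerce(table)
    n1, n2 = t.a + t.b, t.c + t.d
    stat = _wald_matrix(n1, n2)
    t_obs = stat[t.a, t.c]
    rows, cols = np.nonzero(stat >= t_obs - 1e-12)

    def tail(pi):
        pmf1 = binom.pmf(np.arange(n1 + 1), n1, pi)
        pmf2 = binom.pmf(np.arange(n2 + 1), n2, pi)
        return float(np.sum(pmf1[rows] * pmf2[cols]))

    pis = np.arange(grid, 1.0, grid)
    pmf1 = binom.pmf(np.arange(n1 + 1)[None, :], n1, pis[:, None])
    pmf2 = binom.pmf(np.arange(n2 + 1)[None, :], n2, pis[:, None])
    tails = np.einsum("gi,gi->g", pmf1[:, rows], pmf2[:, cols])
    best_i = int(np.argmax(tails))
    best = float(tails[best_i])
    lo = max(grid, pis[best_i] - grid)
    hi = min(1.0 - grid, pis[best_i] + grid)
    if hi > lo:
        res = minimize_scalar(lambda p: -tail(p), bounds=(lo, hi),
                              method="bounded")
        best = max(best, float(-res.fun))
    return min(1.0, best)
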