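"""Self-contained nonparametric two-group and 2x2 tests.

These are the tests behind the group-comparison tables: Mann-Whitney U
for continuous variables and, for 2x2 frequency tables, Fisher's exact
test (probability-mass two-sided definition) and the Yates-corrected
chi-square.  They are implemented from first principles — exact integer
enumeration where feasible — so every p-value is auditable; independent
library implementations serve as oracles in the test suite only.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import chi2_sf_1df, norm_sf

#: largest pooled sample for which the exact Mann-Whitney null is enumerated
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int | None = None
    n2: int | None = None
    odds_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing the average rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1 = len(x)
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x, y, exact_limit: int = EXACT_MW_LIMIT) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Ties contribute 0.5 to U.  When the pooled sample has no ties and at
    most ``exact_limit`` observations, the p-value is exact by enumeration
    of all rank assignments; otherwise a normal approximation with
    tie-corrected variance and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = _u_statistic(x, y)
    mean_u = n1 * n2 / 2.0

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n <= exact_limit and not has_ties:
        ranks = np.arange(1, n + 1, dtype=float)
        dev = abs(u - mean_u)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            r1 = ranks[list(combo)].sum()
            u_perm = r1 - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mean_u) >= dev - 1e-12:
                count += 1
            total += 1
        return TestResult(u, count / total, "mann-whitney-exact", n1, n2)

    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all pooled values identical
        return TestResult(u, 1.0, "mann-whitney-normal", n1, n2)
    z = max(abs(u - mean_u) - 0.5, 0.0) / math.sqrt(var_u)
    return TestResult(u, min(1.0, 2.0 * norm_sf(z)), "mann-whitney-normal", n1, n2)


def _validate_counts(a: int, b: int, c: int, d: int) -> None:
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("2x2 counts must be non-negative integers")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Two-sided by the probability-mass method: the p-value sums the
    hypergeometric probabilities (fixed margins) of every table whose
    probability does not exceed that of the observed one.  Computed in
    exact integer arithmetic.  Also returns the sample odds ratio ad/bc.
    """
    _validate_counts(a, b, c, d)
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if b * c > 0:
        oratio = (a * d) / (b * c)
    elif a * d > 0:
        oratio = math.inf
    else:
        oratio = math.nan
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1", stacklevel=2)
        return TestResult(float(a), 1.0, "fisher-exact", r1, r2, odds_ratio=oratio)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    # common denominator C(n, c1); compare integer numerators exactly
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    numer = 0
    for i in range(lo, hi + 1):
        w = math.comb(r1, i) * math.comb(r2, c1 - i)
        if w <= obs:
            numer += w
    p = numer / math.comb(n, c1)
    return TestResult(float(a), min(1.0, p), "fisher-exact", r1, r2, odds_ratio=oratio)


def chi2_yates_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Yates continuity-corrected chi-square test (1 df) on [[a, b], [c, d]]."""
    _validate_counts(a, b, c, d)
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if n < 1 or (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square requires all margins to be positive")
    expected = np.outer(row, col) / n
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((adj**2 / expected).sum())
    if b * c > 0:
        oratio = (a * d) / (b * c)
    elif a * d > 0:
        oratio = math.inf
    else:
        oratio = math.nan
    return TestResult(stat, chi2_sf_1df(stat), "chi2-yates", int(row[0]), int(row[1]), odds_ratio=oratio)


def min_expected_cell(a: int, b: int, c: int, d: int) -> float:
    """Smallest expected cell count of the 2x2 table (Cochran's rule input)."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    if n == 0:
        return 0.0
    return float((np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n).min())
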