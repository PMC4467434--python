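"""Statistics layer: Fisher's exact test, cohort frequencies, t-tests and
first-order error propagation.

The two-sided Fisher test follows the probability-ordering convention: with
margins fixed, the p-value sums the hypergeometric probabilities of every
table no more probable than the observed one.  The summation is done in
exact rational arithmetic, so ties are handled without floating-point
ambiguity at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from functools import lru_cache
from typing import NamedTuple, Sequence

from scipy import stats as _scipy_stats


@dataclass(frozen=True)
class ExclusivityTable:
    """2x2 counts: rows = alteration A positive/negative (e.g. SKIL fusion),
    columns = alteration B positive/negative (e.g. ETS overexpression)."""

    a: int  # A+ B+
    b: int  # A+ B-
    c: int  # A- B+
    d: int  # A- B-

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be nonnegative")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@lru_cache(maxsize=100_000)
def _hypergeom_pmf(r1: int, r2: int, c1: int) -> tuple[Fraction, ...]:
    """Exact pmf of cell ``a`` over its support for fixed margins."""
    n = r1 + r2
    total = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return tuple(
        Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), total)
        for a in range(lo, hi + 1)
    )


def fisher_exact_two_sided(table: ExclusivityTable | Sequence[int]) -> float:
    """Two-sided Fisher's exact p-value (probability-ordering rule)."""
    if not isinstance(table, ExclusivityTable):
        table = ExclusivityTable(*table)
    a, b, c, d = table.cells()
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    pmf = _hypergeom_pmf(r1, r2, c1)
    lo = max(0, c1 - r2)
    p_obs = pmf[a - lo]
    p = sum(q for q in pmf if q <= p_obs)
    return float(min(p, Fraction(1)))


def cohort_frequency(n_positive: int, n_total: int) -> float:
    """Percentage positive, rounded half-up to one decimal (1.1 for 6/540)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    pct = Decimal(100 * n_positive) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    defined: bool = True


def ttest_unpaired_two_tailed(group_a: Sequence[float], group_b: Sequence[float],
                              welch: bool = False) -> TTestResult:
    """Unpaired two-tailed t-test; Student's pooled-variance by default,
    Welch by flag.  Zero pooled variance yields an undefined result."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs n >= 2")
    a, b = list(group_a), list(group_b)
    if min(a) == max(a) and min(b) == max(b):  # zero pooled variance
        df = float(len(a) + len(b) - 2)
        return TTestResult(float("nan"), df, float("nan"), defined=False)
    res = _scipy_stats.ttest_ind(group_a, group_b, equal_var=not welch)
    df = float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    if not math.isfinite(t):
        return TTestResult(float("nan"), df, float("nan"), defined=False)
    return TTestResult(t, df, p)


@dataclass(frozen=True)
class PropagatedMean:
    mean: float
    sem: float
    n: int
    components: dict | None = None

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")


def propagate_sem_ratio(num_mean: float, num_sem: float, den_mean: float,
                        den_sem: float, n: int = 2) -> PropagatedMean:
    """s.e.m. of a ratio of means by first-order (delta-method) propagation
    with zero covariance:

        sem(x/y) = |x/y| * sqrt((sx/x)^2 + (sy/y)^2)

    The ``num_mean == 0`` limit reduces to |num_sem / den_mean|.
    """
    if den_mean == 0:
        raise ValueError("den_mean must be nonzero")
    if num_sem < 0 or den_sem < 0:
        raise ValueError("sems must be nonnegative")
    mean = num_mean / den_mean
    if num_mean == 0:
        sem = abs(num_sem / den_mean)
    else:
        sem = abs(mean) * math.sqrt((num_sem / num_mean) ** 2 + (den_sem / den_mean) ** 2)
    return PropagatedMean(
        mean=mean,
        sem=sem,
        n=n,
        components={"num_mean": num_mean, "num_sem": num_sem,
                    "den_mean": den_mean, "den_sem": den_sem},
    )
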