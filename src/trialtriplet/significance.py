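"""Two-sided p-values for 2x2 tables with context-dependent test selection.

Two tests are supported:

* Fisher's exact test, two-sided by the minimum-likelihood rule: the
  p-value sums the point probabilities of every table sharing the observed
  margins whose hypergeometric probability does not exceed that of the
  observed table.
* Pearson's chi-square on 1 df, without continuity correction.

Which test applies depends on the analysis context.  During simulation the
rule is Fisher when N <= 50 or any cell is below 5, chi-square otherwise.
For empirical (published-trial) tables the chi-square is used only for very
large trials, N > 5000 with every cell at least 50; everything else gets
the exact test.

Alpha is fixed at 0.05 throughout the classification machinery; ties at
exactly 0.05 count as significant.  ``is_significant`` accepts an override
for exploratory library use only — every evidence-pattern threshold in this
package is anchored to 0.05.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

from math import comb

from .tables import ContingencyTable2x2, validate_table

__all__ = [
    "ALPHA",
    "TestKind",
    "TestContext",
    "TestResult",
    "fisher_exact_two_sided",
    "pearson_chisq",
    "select_test",
    "is_significant",
]

ALPHA = 0.05


class TestKind(str, enum.Enum):
    FISHER = "fisher_exact"
    CHISQ = "pearson_chisq"


class TestContext(str, enum.Enum):
    EMPIRICAL = "empirical"
    SIMULATION = "simulation"


TestKind.__test__ = False  # not pytest collectables
TestContext.__test__ = False


def is_significant(p_value: float, alpha: float = ALPHA) -> bool:
    return p_value <= alpha


@dataclass(frozen=True)
class TestResult:
    """Outcome of a significance test on one table."""

    p_value: float
    test_used: TestKind
    statistic: float | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return is_significant(self.p_value)


TestResult.__test__ = False  # not a pytest collectable


def _fisher_p(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Minimum-likelihood two-sided Fisher p for cells (a,b,c,d).

    Computed in exact integer arithmetic: every table sharing the margins
    has point probability C(n1,k)C(n2,m-k)/C(N,m), so tables are compared
    by their integer numerators (no float tie tolerance needed; tables
    with p exactly at alpha classify correctly) and the final division is
    the only rounding step.

    Returns ``(p, degenerate)``; a zero row or column margin leaves a
    single achievable table, reported as p = 1 with the degenerate flag.
    """
    n1, n2 = a + b, c + d
    n = n1 + n2
    m = a + c  # event-column margin
    if m == 0 or m == n or n1 == 0 or n2 == 0:
        return 1.0, True
    lo, hi = max(0, m - n2), min(n1, m)
    numerators = [comb(n1, k) * comb(n2, m - k) for k in range(lo, hi + 1)]
    num_obs = numerators[a - lo]
    selected = sum(num for num in numerators if num <= num_obs)
    p = selected / comb(n, m)
    return min(p, 1.0), False


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher's exact test (minimum-likelihood rule)."""
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    p, degen = _fisher_p(*t.cells)
    return TestResult(p_value=p, test_used=TestKind.FISHER, degenerate=degen)


def _chisq_p(a: int, b: int, c: int, d: int) -> tuple[float, float | None, bool]:
    n1, n2 = a + b, c + d
    n = n1 + n2
    m1, m0 = a + c, b + d
    if n1 == 0 or n2 == 0 or m1 == 0 or m0 == 0:
        # a zero margin gives expected counts of 0: the statistic is
        # undefined, flagged rather than silently 0
        return 1.0, None, True
    delta = a * d - b * c
    stat = n * delta * delta / (n1 * n2 * m1 * m0)
    # chi2(1 df) survival function
    p = math.erfc(math.sqrt(stat / 2.0))
    return p, float(stat), False


def pearson_chisq(table) -> TestResult:
    """Pearson chi-square on 1 df, no continuity correction."""
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    p, stat, degen = _chisq_p(*t.cells)
    return TestResult(p_value=p, test_used=TestKind.CHISQ, statistic=stat, degenerate=degen)


def _uses_fisher(a: int, b: int, c: int, d: int, ctx: TestContext) -> bool:
    n = a + b + c + d
    min_cell = min(a, b, c, d)
    if ctx is TestContext.SIMULATION:
        return n <= 50 or min_cell < 5
    # empirical: exact test unless the trial is very large with all cells >= 50
    return not (n > 5000 and min_cell >= 50)


@lru_cache(maxsize=4_000_000)
def _select_cached(a: int, b: int, c: int, d: int, ctx: TestContext) -> TestResult:
    if _uses_fisher(a, b, c, d, ctx):
        p, degen = _fisher_p(a, b, c, d)
        return TestResult(p_value=p, test_used=TestKind.FISHER, degenerate=degen)
    p, stat, degen = _chisq_p(a, b, c, d)
    return TestResult(p_value=p, test_used=TestKind.CHISQ, statistic=stat, degenerate=degen)


def select_test(table, ctx: TestContext = TestContext.EMPIRICAL) -> TestResult:
    """Apply the context-dependent test-selection rule and run the test.

    The result's ``test_used`` records which test was chosen.  Results are
    memoised on the cell counts: fragility toggling and Monte Carlo runs
    revisit the same tables constantly.
    """
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    return _select_cached(t.a, t.b, t.c, t.d, TestContext(ctx))
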