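"""Risk quotient: distance of a 2x2 table from therapeutic neutrality.

The risk quotient is

    RQ = |ad - bc| / (N^2 / 4)

a 0-1 scale measuring how far the table sits from the neutrality boundary
ad = bc (equal event odds in both arms).  RQ = 0 at neutrality; RQ = 1 for
the maximally separated balanced table.  The weak / moderate / strong cut
points (0.075 and 0.227) are the 33rd and 67th percentiles of the RQ
distribution from a prior large-scale simulation over realistic trial
parameters; they ship as constants and may be overridden.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .tables import ContingencyTable2x2, validate_table

__all__ = [
    "RQ_WEAK_CUT",
    "RQ_STRONG_CUT",
    "RobustnessCategory",
    "RobustnessThresholds",
    "RobustnessResult",
    "risk_quotient",
    "classify_robustness",
]

RQ_WEAK_CUT = 0.075
RQ_STRONG_CUT = 0.227


class RobustnessCategory(str, enum.Enum):
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


@dataclass(frozen=True)
class RobustnessThresholds:
    """Cut points for the weak / moderate / strong robustness tertiles.

    weak: RQ < weak_cut; strong: RQ >= strong_cut; moderate between.
    """

    weak_cut: float = RQ_WEAK_CUT
    strong_cut: float = RQ_STRONG_CUT

    def __post_init__(self):
        if not 0.0 < self.weak_cut < self.strong_cut < 1.0:
            raise ValueError(
                f"need 0 < weak_cut < strong_cut < 1, got "
                f"({self.weak_cut}, {self.strong_cut})"
            )


DEFAULT_THRESHOLDS = RobustnessThresholds()


@dataclass(frozen=True)
class RobustnessResult:
    rq: float
    category: RobustnessCategory


def risk_quotient(table) -> float:
    """|ad - bc| / (N^2 / 4), computed in exact integer arithmetic first."""
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    n = t.n_total
    return 4 * abs(t.a * t.d - t.b * t.c) / (n * n)


def classify_robustness(
    rq: float, thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS
) -> RobustnessCategory:
    if not 0.0 <= rq <= 1.0:
        raise ValueError(f"RQ must lie in [0, 1], got {rq}")
    if rq < thresholds.weak_cut:
        return RobustnessCategory.WEAK
    if rq >= thresholds.strong_cut:
        return RobustnessCategory.STRONG
    return RobustnessCategory.MODERATE


def robustness(table, thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS) -> RobustnessResult:
    rq = risk_quotient(table)
    return RobustnessResult(rq=rq, category=classify_robustness(rq, thresholds))
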