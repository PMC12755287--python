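"""Evidence-pattern classification from the (p, MFQ, RQ) triplet.

Three named patterns partition the interesting corners of the evidence
space; two residual categories make the partition exhaustive:

* concordant-positive (CP): p <= 0.05, MFQ > 0.10, RQ >= 0.227 —
  significant, stable, strongly robust.
* significant-fragile-weak (SFW): p <= 0.05, MFQ <= 0.10, RQ < 0.075 —
  significant but fragile and close to neutrality.
* concordant-null: p > 0.05, MFQ > 0.10, RQ < 0.075 — stably
  nonsignificant and near neutrality.
* other_significant / other_nonsignificant: everything else, split by
  significance.

Every trial receives exactly one pattern.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .fragility import FragilityResult, MFQ_FRAGILE_MAX, Stability, fragility_index
from .robustness import (
    DEFAULT_THRESHOLDS,
    RobustnessResult,
    RobustnessThresholds,
    classify_robustness,
    risk_quotient,
)
from .significance import ALPHA, TestContext, TestResult, select_test
from .tables import ContingencyTable2x2, validate_table

__all__ = ["Pattern", "TripletResult", "classify_triplet", "analyze_trial"]


class Pattern(str, enum.Enum):
    CP = "CP"
    SFW = "SFW"
    CONCORDANT_NULL = "concordant_null"
    OTHER_SIGNIFICANT = "other_significant"
    OTHER_NONSIGNIFICANT = "other_nonsignificant"


def classify_triplet(
    p: float,
    mfq: float,
    rq: float,
    thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
) -> Pattern:
    """Assign the evidence pattern for one (p, MFQ, RQ) triplet."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if not 0.0 <= mfq <= 1.0:
        raise ValueError(f"MFQ must lie in [0, 1], got {mfq}")
    category = classify_robustness(rq, thresholds)  # validates rq range
    stable = mfq > MFQ_FRAGILE_MAX
    weak = rq < thresholds.weak_cut
    strong = rq >= thresholds.strong_cut
    if p <= ALPHA:
        if stable and strong:
            return Pattern.CP
        if not stable and weak:
            return Pattern.SFW
        return Pattern.OTHER_SIGNIFICANT
    if stable and weak:
        return Pattern.CONCORDANT_NULL
    return Pattern.OTHER_NONSIGNIFICANT


@dataclass(frozen=True)
class TripletResult:
    """Per-trial significance, fragility and robustness with the pattern label."""

    table: ContingencyTable2x2
    test: TestResult
    fragility: FragilityResult
    robustness: RobustnessResult
    pattern: Pattern

    @property
    def p_value(self) -> float:
        return self.test.p_value

    @property
    def significant(self) -> bool:
        return self.test.significant

    @property
    def mfq(self) -> float:
        return self.fragility.mfq

    @property
    def fq(self) -> float:
        return self.fragility.fq(self.table.n_total)

    @property
    def rq(self) -> float:
        return self.robustness.rq

    @property
    def stability(self) -> Stability:
        return self.fragility.stability

    @property
    def degenerate(self) -> bool:
        return self.test.degenerate


def analyze_trial(
    table,
    ctx: TestContext = TestContext.EMPIRICAL,
    thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
) -> TripletResult:
    """Full evidence triplet for one 2x2 table.

    Runs the context's significance test, the modified-arm fragility
    search, and the risk quotient, then assigns the pattern.  Degenerate
    tables (a zero margin) carry the test's ``degenerate`` flag through.
    """
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    ctx = TestContext(ctx)
    test = select_test(t, ctx)
    frag = fragility_index(t, ctx)
    rq = risk_quotient(t)
    rob = RobustnessResult(rq=rq, category=classify_robustness(rq, thresholds))
    pattern = classify_triplet(test.p_value, frag.mfq, rq, thresholds)
    return TripletResult(table=t, test=test, fragility=frag, robustness=rob, pattern=pattern)
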