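"""Fragility index by outcome toggling in the modified arm, and its quotients.

The fragility index (FI) is the minimum number of single-participant
outcome toggles, applied inside one arm of the trial (the *modified arm*),
needed to move the two-sided p-value across 0.05 — in either direction:
significant trials are toggled until they lose significance, nonsignificant
trials until they gain it (a reverse fragility index, computed with the
same algorithm).

The modified arm is the fewer-events arm; ties go to the smaller arm, and a
full tie goes to arm 1.  Toggles flip outcomes within the modified arm, so
arm sizes never change — only the event / non-event split moves.  The
minimum is taken over the two monotone directions (all toggles add events,
or all remove events); the p-value is recomputed with the context's
test-selection rule after every toggle, since a toggle can move a cell
across the small-cell boundary and switch the test.

MFQ = FI / n_mod normalises FI to the modified arm (0 = maximally fragile,
1 = maximally stable); FQ = FI / N normalises to the whole trial.  When no
achievable split of the modified arm flips the classification, the index is
capped at n_mod (MFQ = 1) and flagged.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .significance import TestContext, select_test
from .tables import ContingencyTable2x2, TableValidationError, validate_table

__all__ = [
    "MFQ_FRAGILE_MAX",
    "Stability",
    "ToggleDirection",
    "FragilityResult",
    "choose_modified_arm",
    "fragility_index",
    "classify_stability",
]

logger = logging.getLogger(__name__)

#: MFQ at or below this is classed fragile; above it, stable.
MFQ_FRAGILE_MAX = 0.10


class Stability(str, enum.Enum):
    FRAGILE = "fragile"
    STABLE = "stable"


class ToggleDirection(str, enum.Enum):
    TO_NONSIGNIFICANT = "to_nonsignificant"
    TO_SIGNIFICANT = "to_significant"


@dataclass(frozen=True)
class FragilityResult:
    fi: int
    modified_arm: int
    n_mod: int
    direction: ToggleDirection
    capped: bool = False
    test_switched: bool = False

    @property
    def mfq(self) -> float:
        return self.fi / self.n_mod

    def fq(self, n_total: int) -> float:
        return self.fi / n_total

    @property
    def stability(self) -> Stability:
        return classify_stability(self.mfq)


def choose_modified_arm(table: ContingencyTable2x2) -> tuple[int, int]:
    """Pick the arm subjected to toggling: fewer events, then smaller, then arm 1.

    Returns ``(arm_id, n_mod)``.
    """
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    if t.a != t.c:
        arm = 1 if t.a < t.c else 2
    elif t.n1 != t.n2:
        arm = 1 if t.n1 < t.n2 else 2
    else:
        arm = 1
    return arm, (t.n1 if arm == 1 else t.n2)


def classify_stability(mfq: float) -> Stability:
    if not 0.0 <= mfq <= 1.0:
        raise ValueError(f"MFQ must lie in [0, 1], got {mfq}")
    return Stability.FRAGILE if mfq <= MFQ_FRAGILE_MAX else Stability.STABLE


def _with_events(t: ContingencyTable2x2, arm: int, e: int) -> ContingencyTable2x2:
    if arm == 1:
        return ContingencyTable2x2(e, t.n1 - e, t.c, t.d)
    return ContingencyTable2x2(t.a, t.b, e, t.n2 - e)


def fragility_index(
    table, ctx: TestContext = TestContext.EMPIRICAL
) -> FragilityResult:
    """Minimum toggles in the modified arm that flip the significance class.

    Scans outward from the observed event split, one toggle at a time in
    both monotone directions, recomputing the context-appropriate test at
    each step, and stops at the first step whose classification differs
    from the original table's.  Capped at ``n_mod`` when no achievable
    split flips.
    """
    t = validate_table(table) if not isinstance(table, ContingencyTable2x2) else table
    ctx = TestContext(ctx)
    arm, n_mod = choose_modified_arm(t)
    if n_mod == 0:
        raise TableValidationError("modified arm is empty; fragility undefined")

    base = select_test(t, ctx)
    base_sig = base.significant
    direction = (
        ToggleDirection.TO_NONSIGNIFICANT if base_sig else ToggleDirection.TO_SIGNIFICANT
    )
    e0 = t.a if arm == 1 else t.c
    test_switched = False

    for k in range(1, n_mod + 1):
        for e in (e0 + k, e0 - k):
            if not 0 <= e <= n_mod:
                continue
            res = select_test(_with_events(t, arm, e), ctx)
            if res.test_used is not base.test_used and not test_switched:
                test_switched = True
                logger.debug(
                    "test switched from %s to %s during toggling of %s",
                    base.test_used.value, res.test_used.value, t.cells,
                )
            if res.significant != base_sig:
                return FragilityResult(
                    fi=k,
                    modified_arm=arm,
                    n_mod=n_mod,
                    direction=direction,
                    capped=False,
                    test_switched=test_switched,
                )
        if e0 + k > n_mod and e0 - k < 0:
            break

    return FragilityResult(
        fi=n_mod,
        modified_arm=arm,
        n_mod=n_mod,
        direction=direction,
        capped=True,
        test_switched=test_switched,
    )
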