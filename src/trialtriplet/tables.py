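"""2x2 contingency-table data model for two-arm binary-outcome trials.

The universal input everywhere in this package is a 2x2 table laid out
rows = arms, columns = event / non-event::

              event   non-event
    arm 1       a         b        (n1 = a + b)
    arm 2       c         d        (n2 = c + d)

All analysis operations require both arms to be non-empty; fragility and
relative risk are undefined otherwise, so empty arms are rejected at
validation rather than propagated as NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "ContingencyTable2x2",
    "ArmSummary",
    "TableValidationError",
    "validate_table",
    "observed_rr",
]


class TableValidationError(ValueError):
    """Raised when four cell counts do not form a usable 2x2 trial table."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts of one two-arm binary-outcome trial.

    Attributes
    ----------
    a, b : int
        Event / non-event counts in arm 1.
    c, d : int
        Event / non-event counts in arm 2.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def min_cell(self) -> int:
        return min(self.cells)

    def swap_arms(self) -> "ContingencyTable2x2":
        """Return the table with arm 1 and arm 2 interchanged."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    def arm(self, arm_id: int) -> "ArmSummary":
        if arm_id == 1:
            return ArmSummary(1, self.n1, self.a)
        if arm_id == 2:
            return ArmSummary(2, self.n2, self.c)
        raise ValueError(f"arm_id must be 1 or 2, got {arm_id!r}")


@dataclass(frozen=True)
class ArmSummary:
    """One arm of a trial: its size, event count and event rate."""

    arm_id: int
    n: int
    events: int

    @property
    def event_rate(self) -> float:
        if self.n == 0:
            raise ZeroDivisionError("event rate undefined for an empty arm")
        return self.events / self.n


def _as_nonneg_int(value, name: str) -> int:
    # bool is an int subclass but makes no sense as a cell count
    if isinstance(value, bool):
        raise TableValidationError(f"cell {name} must be an integer, got bool")
    if isinstance(value, (int, np.integer)):
        ivalue = int(value)
    elif isinstance(value, float) and float(value).is_integer():
        ivalue = int(value)
    else:
        raise TableValidationError(
            f"cell {name} must be a non-negative integer, got {value!r}"
        )
    if ivalue < 0:
        raise TableValidationError(f"cell {name} is negative: {ivalue}")
    return ivalue


def validate_table(
    a, b=None, c=None, d=None, *, require_both_arms: bool = True
) -> ContingencyTable2x2:
    """Validate four cell counts and return a :class:`ContingencyTable2x2`.

    Accepts either four scalars or a single iterable of four values.
    Negative or non-integer cells raise :class:`TableValidationError`;
    whole-valued floats (e.g. from a CSV parsed as float) are accepted.

    Parameters
    ----------
    require_both_arms
        When True (default), tables with an empty arm are rejected:
        fragility and relative risk are undefined for them.
    """
    if b is None and c is None and d is None:
        if isinstance(a, ContingencyTable2x2):
            a, b, c, d = a.cells
        else:
            try:
                a, b, c, d = tuple(a)  # type: ignore[misc]
            except (TypeError, ValueError) as exc:
                raise TableValidationError(
                    "expected four cell counts (a, b, c, d)"
                ) from exc
    cells = tuple(
        _as_nonneg_int(v, name) for v, name in zip((a, b, c, d), "abcd")
    )
    table = ContingencyTable2x2(*cells)
    if table.n_total < 1:
        raise TableValidationError("all-zero table: total sample size must be >= 1")
    if require_both_arms and (table.n1 == 0 or table.n2 == 0):
        raise TableValidationError(
            f"empty arm (n1={table.n1}, n2={table.n2}): analysis requires both arms"
        )
    return table


def observed_rr(table: ContingencyTable2x2) -> float:
    """Observed relative risk (arm-1 event rate over arm-2 event rate).

    Returns ``nan`` when arm 2 has zero events (the ratio is undefined);
    raises on an empty arm.
    """
    if table.n1 == 0 or table.n2 == 0:
        raise TableValidationError("relative risk undefined with an empty arm")
    if table.c == 0:
        return float("nan")
    return (table.a / table.n1) / (table.c / table.n2)
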