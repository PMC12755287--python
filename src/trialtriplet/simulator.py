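"""Monte Carlo generation of two-arm binary-outcome trials.

A scenario fixes the total sample size, the allocation ratio
(intervention : control), the control event rate (CER) and the true
relative risk (RR).  Arm 1 is the intervention arm and receives the larger
share under unequal allocation; its event probability is CER x RR, so all
factor combinations of the reference grid remain valid probabilities.
Event counts are independent binomials per arm.

The packaged reference grid crosses five sample sizes (60, 100, 200, 400,
800), three allocations (1:1, 2:1, 3:2), four control event rates (0.05,
0.10, 0.20, 0.40) and six relative risks (1.00, 0.90, 0.80, 0.70, 0.60,
1.10) — 360 scenarios, 2,000 replications each at full scale.

Reproducibility: one master seed; scenario i draws from
``numpy.random.default_rng(SeedSequence(master, spawn_key=(i,)))``, so any
scenario can be re-run independently and the full record stream is
bit-identical for a given grid and master seed.  Each simulated trial is
analysed with the simulation-context test-selection rule, and results are
memoised on the cell counts — replicated scenarios revisit the same tables
constantly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .classification import Pattern, TripletResult, analyze_trial
from .fragility import MFQ_FRAGILE_MAX
from .robustness import DEFAULT_THRESHOLDS, RobustnessThresholds
from .significance import TestContext
from .summary import PrevalenceSummary
from .tables import ContingencyTable2x2

__all__ = [
    "SAMPLE_SIZES",
    "ALLOCATIONS",
    "CONTROL_EVENT_RATES",
    "RELATIVE_RISKS",
    "FULL_REPS",
    "ScenarioSpec",
    "TrialRecord",
    "split_allocation",
    "simulate_trial",
    "reference_grid",
    "run_grid",
    "records_to_dataframe",
    "summarize_grid",
]

logger = logging.getLogger(__name__)

SAMPLE_SIZES: tuple[int, ...] = (60, 100, 200, 400, 800)
ALLOCATIONS: tuple[tuple[int, int], ...] = ((1, 1), (2, 1), (3, 2))
CONTROL_EVENT_RATES: tuple[float, ...] = (0.05, 0.10, 0.20, 0.40)
RELATIVE_RISKS: tuple[float, ...] = (1.00, 0.90, 0.80, 0.70, 0.60, 1.10)
FULL_REPS = 2000


def split_allocation(n_total: int, allocation: tuple[int, int]) -> tuple[int, int]:
    """Split N into arm sizes by the allocation ratio, half-up rounding on arm 1.

    ``allocation`` is (r1, r2) = intervention : control.  Both arms must be
    non-empty after the split.
    """
    r1, r2 = allocation
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"allocation parts must be positive, got {allocation}")
    # n1 = round_half_up(n_total * r1 / (r1 + r2)) in exact integer arithmetic
    s = r1 + r2
    n1 = (2 * n_total * r1 + s) // (2 * s)
    n2 = n_total - n1
    if n1 < 1 or n2 < 1:
        raise ValueError(
            f"allocation {r1}:{r2} of N={n_total} leaves an empty arm ({n1}, {n2})"
        )
    return n1, n2


def _parse_allocation(allocation) -> tuple[int, int]:
    if isinstance(allocation, str):
        parts = allocation.split(":")
        if len(parts) != 2:
            raise ValueError(f"allocation string must look like '2:1', got {allocation!r}")
        return int(parts[0]), int(parts[1])
    r1, r2 = allocation
    return int(r1), int(r2)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell of the factorial design."""

    n_total: int
    allocation: tuple[int, int]
    cer: float
    rr: float
    reps: int = FULL_REPS
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "allocation", _parse_allocation(self.allocation))
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not 0.0 < self.cer < 1.0:
            raise ValueError(f"control event rate must lie in (0, 1), got {self.cer}")
        if self.rr <= 0.0:
            raise ValueError(f"relative risk must be positive, got {self.rr}")
        if self.cer * self.rr > 1.0:
            raise ValueError(
                f"intervention event probability cer*rr = {self.cer * self.rr} exceeds 1"
            )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        split_allocation(self.n_total, self.allocation)  # validates the split

    @property
    def arm_sizes(self) -> tuple[int, int]:
        return split_allocation(self.n_total, self.allocation)

    @property
    def intervention_rate(self) -> float:
        return self.cer * self.rr

    @property
    def allocation_label(self) -> str:
        return f"{self.allocation[0]}:{self.allocation[1]}"


@dataclass(frozen=True)
class TrialRecord:
    scenario: ScenarioSpec
    rep: int
    table: ContingencyTable2x2
    triplet: TripletResult


def simulate_trial(spec: ScenarioSpec, rng: np.random.Generator) -> ContingencyTable2x2:
    """Draw one trial: arm events ~ Binomial(arm size, arm event rate)."""
    n1, n2 = spec.arm_sizes
    a = int(rng.binomial(n1, spec.intervention_rate))
    c = int(rng.binomial(n2, spec.cer))
    return ContingencyTable2x2(a, n1 - a, c, n2 - c)


def reference_grid(
    reps: int = FULL_REPS,
    rr_values: Sequence[float] | None = None,
    sample_sizes: Sequence[int] = SAMPLE_SIZES,
    allocations: Sequence[tuple[int, int]] = ALLOCATIONS,
    cer_values: Sequence[float] = CONTROL_EVENT_RATES,
) -> list[ScenarioSpec]:
    """The packaged factorial grid, optionally restricted to some RR values.

    Factor order (outermost to innermost): sample size, allocation, control
    event rate, relative risk — the scenario index used for sub-seeding
    follows this order.
    """
    rrs = RELATIVE_RISKS if rr_values is None else tuple(rr_values)
    return [
        ScenarioSpec(n_total=n, allocation=alloc, cer=cer, rr=rr, reps=reps)
        for n in sample_sizes
        for alloc in allocations
        for cer in cer_values
        for rr in rrs
    ]


def _scenario_rng(master_seed: int, index: int, spec: ScenarioSpec) -> np.random.Generator:
    if spec.seed is not None:
        return np.random.default_rng(spec.seed)
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return np.random.default_rng(ss)


def run_grid(
    grid: Iterable[ScenarioSpec],
    seed: int = 0,
    ctx: TestContext = TestContext.SIMULATION,
    thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
) -> Iterator[TrialRecord]:
    """Simulate and analyse every scenario of a grid, streaming records.

    Deterministic for a given grid and master seed.  Triplet results are
    cached on cell counts for the duration of the run.
    """
    cache: dict[tuple[int, int, int, int], TripletResult] = {}
    n_degenerate = 0
    for idx, spec in enumerate(grid):
        rng = _scenario_rng(seed, idx, spec)
        n1, n2 = spec.arm_sizes
        a_draws = rng.binomial(n1, spec.intervention_rate, size=spec.reps)
        c_draws = rng.binomial(n2, spec.cer, size=spec.reps)
        for rep in range(spec.reps):
            a, c = int(a_draws[rep]), int(c_draws[rep])
            key = (a, n1 - a, c, n2 - c)
            triplet = cache.get(key)
            if triplet is None:
                table = ContingencyTable2x2(*key)
                triplet = analyze_trial(table, ctx, thresholds)
                cache[key] = triplet
            if triplet.degenerate:
                n_degenerate += 1
            yield TrialRecord(scenario=spec, rep=rep, table=triplet.table, triplet=triplet)
        logger.info(
            "scenario %d done: N=%d %s cer=%g rr=%g reps=%d",
            idx, spec.n_total, spec.allocation_label, spec.cer, spec.rr, spec.reps,
        )
    if n_degenerate:
        logger.info("degenerate tables (zero margin) in run: %d", n_degenerate)


RECORD_COLUMNS = [
    "n_total", "allocation", "cer", "rr", "rep",
    "a", "b", "c", "d",
    "p", "test_used", "significant",
    "fi", "modified_arm", "n_mod", "mfq", "fq",
    "rq", "robustness_category", "pattern", "degenerate",
]


def records_to_dataframe(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Materialise a record stream as one row per trial."""
    rows = []
    for r in records:
        t, tr, sc = r.table, r.triplet, r.scenario
        rows.append((
            sc.n_total, sc.allocation_label, sc.cer, sc.rr, r.rep,
            t.a, t.b, t.c, t.d,
            tr.p_value, tr.test.test_used.value, tr.significant,
            tr.fragility.fi, tr.fragility.modified_arm, tr.fragility.n_mod,
            tr.mfq, tr.fq,
            tr.rq, tr.robustness.category.value, tr.pattern.value, tr.degenerate,
        ))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize_grid(
    records: Iterable[TrialRecord] | pd.DataFrame,
    thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
) -> dict[float, dict]:
    """Per-RR prevalences: significance rate and, among significant trials,
    CP, SFW, strong-robustness and stable fractions, each with a Wilson CI.

    Returns a mapping ``rr -> summary dict``; prevalences among significant
    trials are None (flagged) when an RR level has no significant trials.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if df.empty:
        raise ValueError("no trial records to summarise")
    out: dict[float, dict] = {}
    for rr, sub in df.groupby("rr", sort=True):
        n = len(sub)
        sig = sub[sub["significant"]]
        n_sig = len(sig)
        entry: dict = {
            "n_trials": n,
            "significant": PrevalenceSummary.from_counts(n_sig, n),
        }
        if n_sig == 0:
            entry.update(cp=None, sfw=None, strong=None, stable=None)
            logger.warning("RR=%g: no significant trials; prevalences undefined", rr)
        else:
            entry["cp"] = PrevalenceSummary.from_counts(
                int((sig["pattern"] == Pattern.CP.value).sum()), n_sig
            )
            entry["sfw"] = PrevalenceSummary.from_counts(
                int((sig["pattern"] == Pattern.SFW.value).sum()), n_sig
            )
            entry["strong"] = PrevalenceSummary.from_counts(
                int((sig["rq"] >= thresholds.strong_cut).sum()), n_sig
            )
            entry["stable"] = PrevalenceSummary.from_counts(
                int((sig["mfq"] > MFQ_FRAGILE_MAX).sum()), n_sig
            )
        out[float(rr)] = entry
    return out
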