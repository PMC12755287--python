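"""Trial-dataset CSV I/O, config loading, and the synthetic fixture generator.

The tabular interchange format is plain CSV (UTF-8, header required) with
columns ``trial_id, a, b, c, d``; extra columns (e.g. a clinical ``domain``
label) are carried through as metadata.  Summaries are JSON.

The fixture generator produces a synthetic stand-in for a heterogeneous
literature sample: trial sizes are log-uniform, control event rates
uniform, and true effects drawn from a relative-risk mixture, so the
output exercises every evidence-pattern class.  It emulates breadth of
trial designs, not any particular published collection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classification import Pattern, analyze_trial
from .significance import TestContext
from .simulator import ALLOCATIONS, FULL_REPS, ScenarioSpec, split_allocation
from .summary import PrevalenceSummary
from .tables import ContingencyTable2x2, TableValidationError, validate_table

__all__ = [
    "TrialDatasetRow",
    "FixtureSpec",
    "TrialsCsvError",
    "read_trials_csv",
    "write_trials_csv",
    "generate_fixtures",
    "load_grid_config",
    "packaged_grid_path",
    "packaged_fixture_path",
    "summary_to_jsonable",
]

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"
REQUIRED_COLUMNS = ("trial_id", "a", "b", "c", "d")


class TrialsCsvError(ValueError):
    """Raised for malformed trial CSV files (missing columns, bad rows)."""


@dataclass(frozen=True)
class TrialDatasetRow:
    """One trial of a dataset: id, cell counts, optional metadata."""

    trial_id: str
    table: ContingencyTable2x2
    domain: str | None = None
    context: TestContext = TestContext.EMPIRICAL
    metadata: dict = field(default_factory=dict)


def read_trials_csv(path, skip_invalid: bool = False) -> list[TrialDatasetRow]:
    """Read and validate a trials CSV.

    Any invalid row is reported with its line number; by default a single
    bad row aborts the read, with ``skip_invalid=True`` bad rows are
    dropped (and logged) instead.
    """
    df = pd.read_csv(path)
    missing = [col for col in REQUIRED_COLUMNS if col not in df.columns]
    if missing:
        raise TrialsCsvError(f"{path}: missing required column(s) {missing}")
    extra_cols = [col for col in df.columns if col not in REQUIRED_COLUMNS]
    rows: list[TrialDatasetRow] = []
    errors: list[str] = []
    for i, rec in enumerate(df.to_dict("records")):
        line_no = i + 2  # header is line 1
        try:
            table = validate_table(rec["a"], rec["b"], rec["c"], rec["d"])
        except TableValidationError as exc:
            msg = f"{path}, line {line_no}: {exc}"
            if skip_invalid:
                logger.warning("skipping invalid row: %s", msg)
                continue
            errors.append(msg)
            continue
        meta = {col: rec[col] for col in extra_cols}
        rows.append(
            TrialDatasetRow(
                trial_id=str(rec["trial_id"]),
                table=table,
                domain=meta.get("domain"),
                metadata=meta,
            )
        )
    if errors:
        raise TrialsCsvError(
            "invalid rows:\n" + "\n".join(errors)
        )
    return rows


def write_trials_csv(rows: Sequence[TrialDatasetRow], path) -> None:
    records = []
    for r in rows:
        rec = {"trial_id": r.trial_id, "a": r.table.a, "b": r.table.b,
               "c": r.table.c, "d": r.table.d}
        rec.update(r.metadata)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic fixtures

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic heterogeneous trial collection.

    ``effect_mixture`` lists (relative risk, weight) pairs; weights must
    sum to 1.  Trial sizes are log-uniform on [n_min, n_max]; control
    event rates uniform on [cer_min, cer_max]; allocation ratios drawn
    uniformly from ``allocations``.
    """

    n_trials: int = 200
    effect_mixture: tuple[tuple[float, float], ...] = (
        (1.00, 0.40), (0.80, 0.20), (0.60, 0.15), (0.40, 0.15), (1.50, 0.10),
    )
    n_min: int = 20
    n_max: int = 2000
    cer_min: float = 0.05
    cer_max: float = 0.50
    allocations: tuple[tuple[int, int], ...] = ALLOCATIONS
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        weights = [w for _, w in self.effect_mixture]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("effect-mixture weights must be non-negative and sum to 1")
        if not (2 <= self.n_min <= self.n_max):
            raise ValueError("need 2 <= n_min <= n_max")
        if not (0.0 < self.cer_min <= self.cer_max < 1.0):
            raise ValueError("need 0 < cer_min <= cer_max < 1")
        for rr, _ in self.effect_mixture:
            if rr <= 0 or rr * self.cer_max > 1.0:
                raise ValueError(
                    f"relative risk {rr} with cer_max {self.cer_max} is not a valid rate"
                )


def _draw_fixture_rows(spec: FixtureSpec, seed: int) -> list[TrialDatasetRow]:
    rng = np.random.default_rng(seed)
    rrs = np.array([rr for rr, _ in spec.effect_mixture])
    weights = np.array([w for _, w in spec.effect_mixture])
    rows = []
    for i in range(spec.n_trials):
        n_total = int(round(np.exp(rng.uniform(np.log(spec.n_min), np.log(spec.n_max)))))
        n_total = max(n_total, spec.n_min)
        alloc = spec.allocations[rng.integers(len(spec.allocations))]
        try:
            n1, n2 = split_allocation(n_total, alloc)
        except ValueError:
            n1, n2 = split_allocation(n_total, (1, 1))
        cer = rng.uniform(spec.cer_min, spec.cer_max)
        rr = float(rng.choice(rrs, p=weights))
        a = int(rng.binomial(n1, min(cer * rr, 1.0)))
        c = int(rng.binomial(n2, cer))
        table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
        rows.append(
            TrialDatasetRow(
                trial_id=f"synthetic_{i + 1:04d}",
                table=table,
                metadata={"true_rr": rr, "cer": round(cer, 4)},
            )
        )
    return rows


def generate_fixtures(spec: FixtureSpec, max_retries: int = 5) -> list[TrialDatasetRow]:
    """Deterministically generate a synthetic trial collection.

    The output is checked to contain every evidence-pattern class; if a
    class is missing the draw is repeated with an incremented sub-seed up
    to ``max_retries`` times before erroring.
    """
    wanted = {p.value for p in Pattern}
    for attempt in range(max_retries):
        rows = _draw_fixture_rows(spec, spec.seed + attempt)
        patterns = {
            analyze_trial(r.table, TestContext.EMPIRICAL).pattern.value for r in rows
        }
        if wanted <= patterns:
            if attempt:
                logger.info("fixture generation needed %d retries", attempt)
            return rows
    raise ValueError(
        f"fixture spec could not produce all pattern classes within "
        f"{max_retries} attempts (got {sorted(patterns)}); "
        "increase n_trials or broaden the effect mixture"
    )


# ---------------------------------------------------------------------------
# config files

def packaged_grid_path() -> Path:
    return _DATA_DIR / "reference_grid.yaml"


def packaged_fixture_path() -> Path:
    return _DATA_DIR / "fixtures_default.yaml"


def load_grid_config(path=None, reps: int | None = None,
                     rr_values: Sequence[float] | None = None) -> list[ScenarioSpec]:
    """Load a factorial grid config (YAML) into a list of scenarios.

    Expected keys: ``sample_sizes``, ``allocations`` (``"r1:r2"`` strings),
    ``control_event_rates``, ``relative_risks``, ``reps``.  ``reps`` and
    ``rr_values`` arguments override the file.
    """
    cfg_path = Path(path) if path is not None else packaged_grid_path()
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    required = {"sample_sizes", "allocations", "control_event_rates", "relative_risks"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"{cfg_path}: grid config missing keys {sorted(missing)}")
    use_reps = reps if reps is not None else int(cfg.get("reps", FULL_REPS))
    rrs = [float(r) for r in (rr_values if rr_values is not None else cfg["relative_risks"])]
    return [
        ScenarioSpec(n_total=int(n), allocation=alloc, cer=float(cer), rr=rr, reps=use_reps)
        for n in cfg["sample_sizes"]
        for alloc in cfg["allocations"]
        for cer in cfg["control_event_rates"]
        for rr in rrs
    ]


def load_fixture_config(path=None) -> FixtureSpec:
    cfg_path = Path(path) if path is not None else packaged_fixture_path()
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    if "effect_mixture" in cfg:
        cfg["effect_mixture"] = tuple(
            (float(rr), float(w)) for rr, w in cfg["effect_mixture"]
        )
    if "allocations" in cfg:
        cfg["allocations"] = tuple(
            tuple(int(x) for x in str(a).split(":")) for a in cfg["allocations"]
        )
    return FixtureSpec(**cfg)


# ---------------------------------------------------------------------------
# JSON helpers

def summary_to_jsonable(obj):
    """Recursively convert summaries (PrevalenceSummary, numpy scalars) to
    plain JSON-serialisable structures, keeping both raw proportions and
    one-decimal percentage display strings."""
    if obj is None:
        return None
    if isinstance(obj, PrevalenceSummary):
        return {
            "k": obj.k,
            "n": obj.n,
            "proportion": obj.proportion,
            "percent_display": f"{obj.percent:.1f}",
            "ci_low": obj.ci_low,
            "ci_high": obj.ci_high,
        }
    if isinstance(obj, dict):
        return {str(k): summary_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [summary_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_summary_json(summary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary_to_jsonable(summary), fh, indent=2)
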