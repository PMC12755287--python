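"""Model/Results interface over the evidence-triplet machinery.

Two levels mirror how the framework is used in practice:

* :class:`TrialEvidence` — one 2x2 table; ``fit()`` returns the full
  triplet (p, MFQ, RQ) with the pattern label and a printable summary.
* :class:`EvidenceProfile` — a collection of trials (e.g. a literature
  sample); ``fit()`` computes per-trial triplets and the pattern and
  component prevalences with Wilson intervals, and can compare the
  concordant-positive rate against a simulation-derived expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classification import Pattern, TripletResult, analyze_trial
from .fragility import MFQ_FRAGILE_MAX
from .robustness import DEFAULT_THRESHOLDS, RobustnessThresholds
from .significance import TestContext
from .summary import EnrichmentResult, PrevalenceSummary, enrichment
from .tables import ContingencyTable2x2, validate_table

__all__ = [
    "TrialEvidence",
    "TrialEvidenceResults",
    "EvidenceProfile",
    "EvidenceProfileResults",
]


class TrialEvidence:
    """Evidence-triplet model for a single two-arm binary-outcome trial.

    Parameters
    ----------
    table
        Four cell counts (a, b, c, d) or a :class:`ContingencyTable2x2`.
    context
        Which test-selection rule applies: ``"empirical"`` (default) for
        published tables, ``"simulation"`` for simulated ones.

    Examples
    --------
    >>> res = TrialEvidence((12, 488, 30, 470)).fit()
    >>> res.pattern.value
    'other_significant'
    """

    def __init__(
        self,
        table,
        context: TestContext = TestContext.EMPIRICAL,
        thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
    ):
        self.table = (
            table if isinstance(table, ContingencyTable2x2) else validate_table(table)
        )
        self.context = TestContext(context)
        self.thresholds = thresholds

    def fit(self) -> "TrialEvidenceResults":
        triplet = analyze_trial(self.table, self.context, self.thresholds)
        return TrialEvidenceResults(model=self, triplet=triplet)


@dataclass(frozen=True)
class TrialEvidenceResults:
    model: TrialEvidence
    triplet: TripletResult

    # pass-through accessors
    @property
    def p_value(self) -> float:
        return self.triplet.p_value

    @property
    def mfq(self) -> float:
        return self.triplet.mfq

    @property
    def rq(self) -> float:
        return self.triplet.rq

    @property
    def pattern(self) -> Pattern:
        return self.triplet.pattern

    def summary(self) -> str:
        t, tr = self.model.table, self.triplet
        f = tr.fragility
        lines = [
            "Evidence triplet (p - fragility - robustness)",
            "=" * 46,
            f"table (a,b,c,d)    : {t.cells}   N = {t.n_total}",
            f"test               : {tr.test.test_used.value}"
            + ("  [degenerate]" if tr.test.degenerate else ""),
            f"p-value            : {tr.p_value:.4g}"
            f"   significant: {'yes' if tr.significant else 'no'}",
            f"fragility index    : {f.fi}  (arm {f.modified_arm}, n_mod = {f.n_mod}"
            + (", capped)" if f.capped else ")"),
            f"MFQ                : {tr.mfq:.3f}   ({tr.stability.value})",
            f"FQ                 : {tr.fq:.3f}",
            f"RQ                 : {tr.rq:.3f}   ({tr.robustness.category.value})",
            f"pattern            : {tr.pattern.value}",
        ]
        return "\n".join(lines)


def _prev(k: int, n: int) -> PrevalenceSummary | None:
    return PrevalenceSummary.from_counts(k, n) if n > 0 else None


class EvidenceProfile:
    """Evidence-pattern profile of a collection of trials.

    Build from a list of tables or, more conveniently, from a DataFrame
    with integer columns ``a, b, c, d`` (and an optional ``trial_id``).
    """

    def __init__(
        self,
        tables: Iterable,
        trial_ids: Sequence[str] | None = None,
        context: TestContext = TestContext.EMPIRICAL,
        thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
    ):
        self.tables = [
            t if isinstance(t, ContingencyTable2x2) else validate_table(t)
            for t in tables
        ]
        if not self.tables:
            raise ValueError("EvidenceProfile needs at least one trial")
        if trial_ids is not None and len(trial_ids) != len(self.tables):
            raise ValueError("trial_ids length must match the number of tables")
        self.trial_ids = (
            list(trial_ids)
            if trial_ids is not None
            else [f"trial_{i + 1}" for i in range(len(self.tables))]
        )
        self.context = TestContext(context)
        self.thresholds = thresholds

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        context: TestContext = TestContext.EMPIRICAL,
        thresholds: RobustnessThresholds = DEFAULT_THRESHOLDS,
    ) -> "EvidenceProfile":
        missing = [col for col in ("a", "b", "c", "d") if col not in df.columns]
        if missing:
            raise ValueError(f"DataFrame lacks required columns: {missing}")
        ids = (
            df["trial_id"].astype(str).tolist()
            if "trial_id" in df.columns
            else None
        )
        tables = [
            validate_table(row.a, row.b, row.c, row.d)
            for row in df[["a", "b", "c", "d"]].itertuples(index=False)
        ]
        return cls(tables, trial_ids=ids, context=context, thresholds=thresholds)

    def fit(self) -> "EvidenceProfileResults":
        triplets = [analyze_trial(t, self.context, self.thresholds) for t in self.tables]
        return EvidenceProfileResults(model=self, triplets=triplets)


@dataclass
class EvidenceProfileResults:
    model: EvidenceProfile
    triplets: list[TripletResult]
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self):
        rows = []
        for tid, tr in zip(self.model.trial_ids, self.triplets):
            t = tr.table
            rows.append({
                "trial_id": tid,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "n_total": t.n_total,
                "p": tr.p_value,
                "test_used": tr.test.test_used.value,
                "significant": tr.significant,
                "fi": tr.fragility.fi,
                "modified_arm": tr.fragility.modified_arm,
                "n_mod": tr.fragility.n_mod,
                "mfq": tr.mfq,
                "fq": tr.fq,
                "rq": tr.rq,
                "robustness_category": tr.robustness.category.value,
                "pattern": tr.pattern.value,
                "degenerate": tr.degenerate,
            })
        self.frame = pd.DataFrame(rows)

    # ---- prevalences -----------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.triplets)

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    def pattern_counts(self) -> dict[str, int]:
        counts = dict.fromkeys((p.value for p in Pattern), 0)
        counts.update(self.frame["pattern"].value_counts().to_dict())
        return counts

    def prevalences(self) -> dict[str, PrevalenceSummary | None]:
        """Pattern and component prevalences with Wilson 95% intervals.

        Among significant trials: CP, SFW, fragile (MFQ <= 0.10), weak
        (RQ below the weak cut) and strong robustness.  Among
        nonsignificant trials: the concordant-null pattern and stability.
        """
        df = self.frame
        sig = df[df["significant"]]
        nonsig = df[~df["significant"]]
        n_sig, n_non = len(sig), len(nonsig)
        thr = self.model.thresholds
        return {
            "significant": _prev(n_sig, len(df)),
            "cp_among_significant": _prev(int((sig["pattern"] == "CP").sum()), n_sig),
            "sfw_among_significant": _prev(int((sig["pattern"] == "SFW").sum()), n_sig),
            "fragile_among_significant": _prev(
                int((sig["mfq"] <= MFQ_FRAGILE_MAX).sum()), n_sig
            ),
            "weak_among_significant": _prev(
                int((sig["rq"] < thr.weak_cut).sum()), n_sig
            ),
            "strong_among_significant": _prev(
                int((sig["rq"] >= thr.strong_cut).sum()), n_sig
            ),
            "concordant_null_among_nonsignificant": _prev(
                int((nonsig["pattern"] == "concordant_null").sum()), n_non
            ),
            "stable_among_nonsignificant": _prev(
                int((nonsig["mfq"] > MFQ_FRAGILE_MAX).sum()), n_non
            ),
        }

    def medians(self) -> dict[str, dict[str, float]]:
        """Median and IQR of MFQ and RQ, stratified by significance."""
        out: dict[str, dict[str, float]] = {}
        for label, sub in (
            ("significant", self.frame[self.frame["significant"]]),
            ("nonsignificant", self.frame[~self.frame["significant"]]),
        ):
            if len(sub) == 0:
                continue
            out[label] = {
                "mfq_median": float(sub["mfq"].median()),
                "mfq_q1": float(sub["mfq"].quantile(0.25)),
                "mfq_q3": float(sub["mfq"].quantile(0.75)),
                "rq_median": float(sub["rq"].median()),
                "rq_q1": float(sub["rq"].quantile(0.25)),
                "rq_q3": float(sub["rq"].quantile(0.75)),
            }
        return out

    def cp_enrichment(self, expected_p0: float) -> EnrichmentResult:
        """Exact-binomial comparison of the CP rate among significant trials
        against a reference rate (e.g. a null-simulation expectation)."""
        sig = self.frame[self.frame["significant"]]
        if len(sig) == 0:
            raise ValueError("no significant trials; CP prevalence undefined")
        k = int((sig["pattern"] == "CP").sum())
        return enrichment(k, len(sig), expected_p0)

    def summary(self) -> str:
        prev = self.prevalences()
        lines = [
            "Evidence-pattern profile",
            "=" * 58,
            f"trials: {self.n_trials}   significant (p <= 0.05): "
            f"{prev['significant'].display()}",
            "",
            "among significant trials:",
        ]
        for key, label in (
            ("cp_among_significant", "concordant-positive (CP)"),
            ("sfw_among_significant", "significant-fragile-weak"),
            ("fragile_among_significant", "fragile (MFQ <= 0.10)"),
            ("weak_among_significant", "weak robustness"),
            ("strong_among_significant", "strong robustness"),
        ):
            p = prev[key]
            lines.append(f"  {label:<26}: {p.display() if p else 'undefined (none)'}")
        lines += ["", "among nonsignificant trials:"]
        for key, label in (
            ("concordant_null_among_nonsignificant", "concordant-null"),
            ("stable_among_nonsignificant", "stable (MFQ > 0.10)"),
        ):
            p = prev[key]
            lines.append(f"  {label:<26}: {p.display() if p else 'undefined (none)'}")
        return "\n".join(lines)
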