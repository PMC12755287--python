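"""Prevalence summaries, Wilson intervals, exact binomial enrichment tests.

Prevalences (e.g. the fraction of significant trials showing a pattern)
are reported as k/n with a 95% Wilson score interval.  Enrichment of an
observed prevalence over a simulation-derived expectation is assessed with
the exact binomial test (two-sided by the minimum-likelihood rule, the
same convention scipy's ``binomtest`` implements) and summarised as a fold
elevation.  ``fold_elevation`` has a display variant that forms the ratio
of the two percentages after rounding each to one decimal, matching how
such folds are conventionally quoted alongside one-decimal percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PrevalenceSummary",
    "EnrichmentResult",
    "wilson_ci",
    "exact_binomial_two_sided",
    "fold_elevation",
]


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1:
        raise ValueError("Wilson interval requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # Wilson bounds are exactly 0 at k=0 and 1 at k=n; drop float dust
    low = 0.0 if k == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if k == n else min(max(float(high), 0.0), 1.0)
    return low, high


@dataclass(frozen=True)
class PrevalenceSummary:
    """A proportion k/n with its Wilson 95% confidence bounds."""

    k: int
    n: int
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: int, n: int, conf: float = 0.95) -> "PrevalenceSummary":
        low, high = wilson_ci(k, n, conf)
        return cls(k=k, n=n, ci_low=low, ci_high=high)

    @property
    def proportion(self) -> float:
        return self.k / self.n

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion

    def display(self) -> str:
        return (
            f"{self.percent:.1f}% ({self.k}/{self.n}; "
            f"95% CI = {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}%)"
        )


def exact_binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value for k successes in n at rate p0."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if p0 <= 0.0 or p0 >= 1.0:
        # degenerate reference rate: outcome is certain under p0
        if (p0 <= 0.0 and k == 0) or (p0 >= 1.0 and k == n):
            return 1.0
        return 0.0
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def exact_binomial_one_sided(k: int, n: int, p0: float, alternative: str = "greater") -> float:
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    return float(binomtest(k, n, p0, alternative=alternative).pvalue)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: PrevalenceSummary
    expected_p0: float
    fold: float
    fold_display: float
    binom_p: float


def fold_elevation(observed: float, expected: float, display: bool = False) -> float:
    """Ratio of an observed proportion to an expected one.

    With ``display=True`` both proportions are first expressed as
    percentages rounded to one decimal, and the ratio is then rounded to
    one decimal — the convention used when quoting folds computed from
    printed percentages.
    """
    if expected <= 0:
        raise ValueError("fold elevation undefined for expected <= 0")
    if display:
        obs_pct = round(100.0 * observed, 1)
        exp_pct = round(100.0 * expected, 1)
        if exp_pct <= 0:
            raise ValueError("rounded expected percentage is 0; fold undefined")
        return round(obs_pct / exp_pct, 1)
    return observed / expected


def enrichment(k: int, n: int, expected_p0: float) -> EnrichmentResult:
    """Observed prevalence vs. a reference rate: Wilson CI, fold, exact p."""
    obs = PrevalenceSummary.from_counts(k, n)
    return EnrichmentResult(
        observed=obs,
        expected_p0=expected_p0,
        fold=fold_elevation(obs.proportion, expected_p0),
        fold_display=fold_elevation(obs.proportion, expected_p0, display=True),
        binom_p=exact_binomial_two_sided(k, n, expected_p0),
    )
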