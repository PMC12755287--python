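"""Independent oracles used by the test suite.

These deliberately avoid the package's own p-value and fragility code
paths: Fisher p-values come from exact rational enumeration (or scipy),
chi-square p-values from scipy.stats.chi2_contingency, and the fragility
index from an exhaustive scan over every achievable event split of the
modified arm.
"""

from fractions import Fraction
from math import comb

import scipy.stats as st


def fisher_p_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided minimum-likelihood Fisher p as an exact rational."""
    n1, n2 = a + b, c + d
    n = n1 + n2
    m = a + c
    if m == 0 or m == n or n1 == 0 or n2 == 0:
        return Fraction(1)
    denom = comb(n, m)
    pmf = {
        k: Fraction(comb(n1, k) * comb(n2, m - k), denom)
        for k in range(max(0, m - n2), min(n1, m) + 1)
    }
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs)


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    return float(fisher_p_exact(a, b, c, d))


def chisq_p_oracle(a: int, b: int, c: int, d: int) -> float:
    stat, p, _, _ = st.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(p)


def significant_oracle(a: int, b: int, c: int, d: int, ctx: str) -> bool:
    """Re-derive the test-selection rule and significance call from scratch."""
    n = a + b + c + d
    min_cell = min(a, b, c, d)
    if ctx == "simulation":
        use_fisher = n <= 50 or min_cell < 5
    else:
        use_fisher = not (n > 5000 and min_cell >= 50)
    if use_fisher:
        # exact rational p so tables sitting exactly at alpha classify right
        p = float(fisher_p_exact(a, b, c, d))
    else:
        p = chisq_p_oracle(a, b, c, d)
    return p <= 0.05


def fi_oracle(a: int, b: int, c: int, d: int, ctx: str) -> tuple[int, bool]:
    """Brute-force fragility index over every event split of the modified arm.

    Returns (fi, capped).  The modified arm is the fewer-events arm,
    smaller arm on an event tie, arm 1 on a full tie.
    """
    n1, n2 = a + b, c + d
    if a != c:
        arm = 1 if a < c else 2
    elif n1 != n2:
        arm = 1 if n1 < n2 else 2
    else:
        arm = 1
    n_mod = n1 if arm == 1 else n2
    e0 = a if arm == 1 else c
    base = significant_oracle(a, b, c, d, ctx)
    best = None
    for e in range(n_mod + 1):
        if e == e0:
            continue
        cells = (e, n1 - e, c, d) if arm == 1 else (a, b, e, n2 - e)
        if significant_oracle(*cells, ctx) != base:
            dist = abs(e - e0)
            if best is None or dist < best:
                best = dist
    if best is None:
        return n_mod, True
    return best, False


def binom_two_sided_oracle(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided exact binomial p by full enumeration."""
    pmf = [st.binom.pmf(i, n, p0) for i in range(n + 1)]
    p_obs = pmf[k]
    return float(sum(p for p in pmf if p <= p_obs * (1 + 1e-7)))
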