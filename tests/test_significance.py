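from fractions import Fraction
from math import comb

import pytest
import scipy.stats
from hypothesis import given

from trialtriplet import (
    ContingencyTable2x2,
    TestContext,
    TestKind,
    fisher_exact_two_sided,
    pearson_chisq,
    select_test,
    validate_table,
)

from _oracles import chisq_p_oracle, fisher_p_oracle
from conftest import tables_st


class TestFisher:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((5, 5, 5, 5), 1.0),
            # frozen from the exact rational enumeration oracle
            ((1, 9, 9, 1), 0.001093333910671372),
            ((0, 10, 5, 5), 0.032507739938080496),
        ],
    )
    def test_known_values(self, cells, expected):
        assert fisher_exact_two_sided(cells).p_value == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margin_is_p1_flagged(self):
        res = fisher_exact_two_sided((0, 10, 0, 10))
        assert res.p_value == 1.0 and res.degenerate

    def test_exhaustive_agreement_with_enumeration_oracle_n_le_30(self):
        """Every table with N <= 30 matches the rational-arithmetic oracle.

        Tables are grouped by margins so each hypergeometric family is
        enumerated once.
        """
        for n in range(2, 31):
            for n1 in range(1, n):
                n2 = n - n1
                for m in range(0, n + 1):
                    lo, hi = max(0, m - n2), min(n1, m)
                    if lo > hi:
                        continue
                    denom = comb(n, m)
                    pmf = {
                        k: Fraction(comb(n1, k) * comb(n2, m - k), denom)
                        for k in range(lo, hi + 1)
                    }
                    for a in range(lo, hi + 1):
                        expected = (
                            1.0
                            if m in (0, n)
                            else float(sum(p for p in pmf.values() if p <= pmf[a]))
                        )
                        got = fisher_exact_two_sided(
                            ContingencyTable2x2(a, n1 - a, m - a, n2 - (m - a))
                        ).p_value
                        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (
                            a, n1 - a, m - a, n2 - (m - a),
                        )

    @given(tables_st(max_n=60))
    def test_matches_scipy(self, t):
        """Independent cross-check against scipy's Fisher implementation."""
        ours = fisher_exact_two_sided(t).p_value
        theirs = scipy.stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
        assert ours == pytest.approx(float(theirs), rel=1e-9, abs=1e-12)

    @given(tables_st())
    def test_symmetry_invariances(self, t):
        p = fisher_exact_two_sided(t).p_value
        assert fisher_exact_two_sided(t.swap_arms()).p_value == pytest.approx(p, rel=1e-9)
        flipped = ContingencyTable2x2(t.b, t.a, t.d, t.c)
        assert fisher_exact_two_sided(flipped).p_value == pytest.approx(p, rel=1e-9)


class TestPearsonChisq:
    def test_statistic_zero_when_odds_equal(self):
        res = pearson_chisq((50, 50, 50, 50))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_statistic(self):
        res = pearson_chisq((60, 40, 40, 60))
        assert res.statistic == pytest.approx(8.0)
        assert res.p_value == pytest.approx(0.004677734981063, rel=1e-9)

    def test_zero_margin_degenerate(self):
        res = pearson_chisq((0, 100, 0, 100))
        assert res.degenerate and res.p_value == 1.0

    @given(tables_st(max_n=80))
    def test_matches_scipy_uncorrected(self, t):
        if min(t.a + t.c, t.b + t.d) == 0:
            return
        ours = pearson_chisq(t)
        stat, p, _, _ = scipy.stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        )
        assert ours.statistic == pytest.approx(float(stat), rel=1e-9, abs=1e-12)
        assert ours.p_value == pytest.approx(float(p), rel=1e-7, abs=1e-12)

    @given(tables_st())
    def test_statistic_zero_iff_neutral(self, t):
        if min(t.a + t.c, t.b + t.d) == 0:
            return
        res = pearson_chisq(t)
        assert (res.statistic == 0.0) == (t.a * t.d == t.b * t.c)


class TestSelectTest:
    @pytest.mark.parametrize(
        "cells, ctx, expected",
        [
            # simulation: Fisher when N <= 50 or any cell < 5
            ((2, 28, 6, 24), TestContext.SIMULATION, TestKind.FISHER),
            ((10, 15, 10, 15), TestContext.SIMULATION, TestKind.FISHER),
            ((40, 360, 30, 370), TestContext.SIMULATION, TestKind.CHISQ),
            # empirical: chi-square only for N > 5000 with all cells >= 50
            ((60, 2940, 90, 2910), TestContext.EMPIRICAL, TestKind.CHISQ),
            ((40, 2960, 90, 2910), TestContext.EMPIRICAL, TestKind.FISHER),
            ((60, 2440, 90, 2410), TestContext.EMPIRICAL, TestKind.FISHER),
        ],
    )
    def test_selection_rules(self, cells, ctx, expected):
        assert select_test(validate_table(*cells), ctx).test_used is expected

    @given(tables_st(max_n=70))
    def test_selected_p_matches_named_test(self, t):
        for ctx in TestContext:
            res = select_test(t, ctx)
            direct = (
                fisher_exact_two_sided(t)
                if res.test_used is TestKind.FISHER
                else pearson_chisq(t)
            )
            assert res.p_value == direct.p_value

    def test_tie_at_alpha_counts_significant(self):
        from trialtriplet.significance import TestResult

        assert TestResult(p_value=0.05, test_used=TestKind.FISHER).significant
        assert not TestResult(p_value=0.0500001, test_used=TestKind.FISHER).significant
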