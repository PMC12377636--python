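"""Hypergeometric probabilities, stratum counting and charge breakdowns."""

from collections import Counter
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from fluorodist.enrichment import (
    StratumSpec,
    build_enrichment_table,
    charge_breakdown,
    hypergeom_pmf,
    hypergeom_upper_tail,
    round_half_away,
)
from fluorodist.errors import CountConsistencyError, StratumSpecError


def enumeration_pmf(m, y, x, n):
    """Oracle: exact pmf by enumerating every size-n subset of a population
    of y items whose first x are successes."""
    combos = list(combinations(range(y), n))
    hits = sum(1 for c in combos if sum(1 for i in c if i < x) == m)
    return Fraction(hits, len(combos))


class TestHypergeomAgainstEnumeration:
    @pytest.mark.parametrize("y,x,n", [(10, 4, 5), (8, 8, 3), (9, 0, 4), (7, 3, 7), (6, 5, 2)])
    def test_pmf_and_tail_match_subset_enumeration(self, y, x, n):
        for m in range(0, min(x, n) + 1):
            exact_pmf = enumeration_pmf(m, y, x, n)
            exact_tail = sum(
                enumeration_pmf(k, y, x, n) for k in range(m, min(x, n) + 1)
            )
            assert hypergeom_pmf(m, y, x, n) == pytest.approx(float(exact_pmf), abs=1e-14)
            assert hypergeom_upper_tail(m, y, x, n) == pytest.approx(
                float(exact_tail), abs=1e-14
            )

    def test_worked_example(self):
        # (m=2, y=10, x=4, n=5): enumeration gives C(4,2)*C(6,3)/C(10,5)
        assert hypergeom_pmf(2, 10, 4, 5) == pytest.approx(
            float(enumeration_pmf(2, 10, 4, 5))
        )


class TestHypergeomProperties:
    def test_no_successes_possible(self):
        assert hypergeom_pmf(0, 20, 0, 7) == pytest.approx(1.0)

    def test_tail_is_one_at_support_floor(self):
        assert hypergeom_upper_tail(0, 50, 20, 10) == 1.0
        # floor above zero: n - (y - x) = 5, P(X >= 5) must be 1
        assert hypergeom_upper_tail(5, 20, 15, 10) == pytest.approx(1.0)

    def test_pmf_zero_below_support_floor(self):
        assert hypergeom_pmf(0, 20, 15, 10) == 0.0

    @given(st.data())
    @settings(derandomize=True, max_examples=200)
    def test_symmetry_in_draws_and_successes(self, data):
        y = data.draw(st.integers(1, 120))
        x = data.draw(st.integers(0, y))
        n = data.draw(st.integers(0, y))
        lo = max(0, n - (y - x))
        m = data.draw(st.integers(lo, min(x, n)))
        assert hypergeom_pmf(m, y, x, n) == pytest.approx(
            hypergeom_pmf(m, y, n, x), rel=1e-10, abs=1e-300
        )

    @given(st.data())
    @settings(derandomize=True, max_examples=200)
    def test_matches_scipy(self, data):
        y = data.draw(st.integers(1, 400))
        x = data.draw(st.integers(0, y))
        n = data.draw(st.integers(0, y))
        lo = max(0, n - (y - x))
        m = data.draw(st.integers(lo, min(x, n)))
        assert hypergeom_pmf(m, y, x, n) == pytest.approx(
            scipy_hypergeom.pmf(m, y, x, n), rel=1e-9, abs=1e-300
        )
        assert hypergeom_upper_tail(m, y, x, n) == pytest.approx(
            scipy_hypergeom.sf(m - 1, y, x, n), rel=1e-9, abs=1e-300
        )

    @pytest.mark.parametrize(
        "m,y,x,n", [(5, 10, 4, 6), (3, 10, 5, 2), (2, 5, 3, 6), (1, 4, 5, 2)]
    )
    def test_infeasible_counts_rejected(self, m, y, x, n):
        with pytest.raises(CountConsistencyError):
            hypergeom_pmf(m, y, x, n)
        with pytest.raises(CountConsistencyError):
            hypergeom_upper_tail(m, y, x, n)


class TestBuildEnrichmentTable:
    def test_toy_hand_count(self, toy_scored):
        rows = build_enrichment_table(
            toy_scored, [StratumSpec("liver", "VI", "pentamethine")]
        )
        r = rows[0]
        assert (r.x, r.y, r.m, r.n) == (4, 6, 2, 3)
        assert r.p_pmf == pytest.approx(float(enumeration_pmf(2, 6, 4, 3)))

    def test_charge_filter_restricts_region_counts_only(self, toy_scored):
        scored = toy_scored.copy()
        scored.loc[scored["compound_id"] == "C2", "net_charge"] = 0  # in-region, low
        rows = build_enrichment_table(
            scored, [StratumSpec("liver", "VI", "pentamethine", charge="positive")]
        )
        r = rows[0]
        # type totals keep all 6; the zwitterion drops out of n only
        assert (r.x, r.y, r.m, r.n) == (4, 6, 2, 2)

    def test_empty_stratum_has_unit_pmf(self, toy_scored):
        rows = build_enrichment_table(toy_scored, [StratumSpec("liver", "IV", "pentamethine")])
        r = rows[0]
        assert (r.m, r.n) == (0, 0)
        assert r.p_pmf == pytest.approx(1.0)
        assert r.p_tail == pytest.approx(1.0)

    def test_unknown_stratum_rejected(self, toy_scored):
        with pytest.raises(StratumSpecError):
            build_enrichment_table(toy_scored, [StratumSpec("liver", "IX", "pentamethine")])
        with pytest.raises(StratumSpecError):
            build_enrichment_table(toy_scored, [StratumSpec("liver", "VI", "bodipy")])
        with pytest.raises(StratumSpecError):
            build_enrichment_table(
                toy_scored, [StratumSpec("liver", "VI", "pentamethine", charge="sideways")]
            )

    def test_default_library_enriched_stratum_significant(self, default_results):
        pooled = build_enrichment_table(
            default_results.scored, [StratumSpec("liver", "VI", charge="positive")]
        )[0]
        assert pooled.p_tail < 1e-3


class TestChargeBreakdown:
    @pytest.fixture
    def charged_scored(self):
        return pd.DataFrame(
            {
                "compound_id": [f"C{i}" for i in range(8)],
                "organ": ["kidney"] * 8,
                "skeleton": ["heptamethine"] * 8,
                "net_charge": [1, 1, 1, 2, 2, 0, -1, 1],
                "region": ["III"] * 7 + ["II"],
                "high": [True, True, False, True, False, False, True, True],
            }
        )

    def test_per_bin_counts_and_percentages(self, charged_scored):
        rows = charge_breakdown(charged_scored, "kidney", "III", "heptamethine")
        by_charge = {r.net_charge: r for r in rows}
        assert set(by_charge) == {-1, 0, 1, 2}  # charge +3 bin absent: omitted
        assert (by_charge[1].n_in_bin, by_charge[1].n_high_in_bin) == (3, 2)
        assert by_charge[1].pct_high == pytest.approx(100 * 2 / 3)
        assert by_charge[0].pct_high == 0.0

    def test_breakdown_consistent_with_enrichment_counts(self, default_results):
        rows = charge_breakdown(default_results.scored, "liver", "VI", "heptamethine")
        stratum = build_enrichment_table(
            default_results.scored, [StratumSpec("liver", "VI", "heptamethine", "positive")]
        )[0]
        pos = [r for r in rows if r.net_charge > 0]
        assert sum(r.n_in_bin for r in pos) == stratum.n
        assert sum(r.n_high_in_bin for r in pos) == stratum.m


@pytest.mark.parametrize(
    "value,expected",
    [(70.45, 70), (85.04, 85), (83.33, 83), (82.28, 82), (0.5, 1), (-0.5, -1), (61.09, 61)],
)
def test_round_half_away(value, expected):
    assert round_half_away(value) == expected
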