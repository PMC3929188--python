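"""Binomial tail statistic, category scoring, ranking, and BH adjustment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom as scipy_binom

from oryzadiff import (
    CategoryMap,
    bh_adjust,
    binomial_tail,
    enrich_categories,
    family_regulation_fraction,
    make_universe,
    rank_results,
)
from oryzadiff.enrichment import format_report


def exact_tail(k, n, p_num, p_den):
    """Closed-form upper tail by exact rational summation (the oracle)."""
    p = Fraction(p_num, p_den)
    return float(sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)))


class TestBinomialTail:
    def test_k_zero_is_whole_distribution(self):
        assert binomial_tail(0, 10, 0.3) == 1.0

    def test_enumerated_example(self):
        # 26 of the 32 equally likely length-5 coin sequences have >= 2 heads
        assert binomial_tail(2, 5, 0.5) == pytest.approx(26 / 32, abs=1e-12)

    @pytest.mark.parametrize("p_num,p_den", [(1, 10), (1, 2), (9, 10)])
    def test_matches_exact_rational_oracle(self, p_num, p_den):
        for n in range(1, 13):
            for k in range(n + 1):
                expected = exact_tail(k, n, p_num, p_den)
                assert binomial_tail(k, n, p_num / p_den) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(1, 500), st.data())
    def test_agrees_with_scipy_survival_function(self, n, data):
        k = data.draw(st.integers(0, n))
        p = data.draw(st.floats(1e-6, 1 - 1e-6))
        ours = binomial_tail(k, n, p)
        ref = float(scipy_binom.sf(k - 1, n, p))
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    @given(st.integers(1, 200), st.floats(0.01, 0.99))
    def test_non_increasing_in_k(self, n, p):
        tails = [binomial_tail(k, n, p) for k in range(n + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_lower_tail_complement(self):
        up = binomial_tail(4, 10, 0.3)
        lo = binomial_tail(3, 10, 0.3, lower=True)
        assert up + lo == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, bad_p):
        with pytest.raises(ValueError):
            binomial_tail(1, 5, bad_p)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(6, 5, 0.5)


class TestEnrichCategories:
    def _universe(self, n):
        return make_universe([f"g{i}" for i in range(n)])

    def test_fully_regulated_category_closed_form(self):
        universe = self._universe(1000)
        regulated = [f"g{i}" for i in range(100)]
        cat = CategoryMap("GO:X", "all in", "GO", frozenset(regulated[:10]))
        res = enrich_categories(universe, regulated, [cat])
        # all 10 members regulated at background rate 0.1 -> p = 0.1^10
        assert res.loc[0, "p_value"] == pytest.approx(1e-10, rel=1e-9)
        assert res.loc[0, "observed"] == 10
        assert res.loc[0, "ratio"] == 1.0

    def test_disjoint_category_scores_one(self):
        universe = self._universe(1000)
        regulated = [f"g{i}" for i in range(100)]
        cat = CategoryMap("GO:Y", "none in", "GO", frozenset({"g500", "g501"}))
        res = enrich_categories(universe, regulated, [cat])
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "ratio"] == 0.0

    def test_empty_regulated_set_is_an_error(self):
        universe = self._universe(10)
        cat = CategoryMap("GO:Z", "z", "GO", frozenset({"g1"}))
        with pytest.raises(ValueError):
            enrich_categories(universe, [], [cat])

    def test_category_outside_universe_skipped(self):
        universe = self._universe(10)
        cats = [
            CategoryMap("GO:in", "in", "GO", frozenset({"g1", "g2"})),
            CategoryMap("GO:out", "out", "GO", frozenset({"zz"})),
        ]
        res = enrich_categories(universe, ["g1"], cats)
        assert list(res["category_id"]) == ["GO:in"]

    def test_alternative_parameterisation_runs(self):
        universe = self._universe(1000)
        regulated = [f"g{i}" for i in range(100)]
        cat = CategoryMap("GO:X", "x", "GO", frozenset({"g0", "g1", "g500"}))
        a = enrich_categories(universe, regulated, [cat], parameterisation="pathway_n")
        b = enrich_categories(universe, regulated, [cat], parameterisation="regulated_n")
        assert a.loc[0, "observed"] == b.loc[0, "observed"] == 2
        assert a.loc[0, "p_value"] != b.loc[0, "p_value"]

    def test_observed_counts_match_direct_intersection(self, small_study):
        # sum rule: every regulated gene is counted once per category membership
        universe = make_universe(small_study.genes)
        regulated = sorted(small_study.truth.regulated.index)
        res = enrich_categories(universe, regulated, small_study.categories)
        direct = {
            c.category_id: len(c.members & set(regulated)) for c in small_study.categories
        }
        for _, row in res.iterrows():
            assert row["observed"] == direct[row["category_id"]]
        assert res["observed"].sum() == sum(direct.values())


class TestRanking:
    def test_ascending_p(self):
        df = pd.DataFrame(
            {"category_id": ["a", "b"], "observed": [3, 5], "p_value": [1e-5, 1e-7]}
        )
        ranked = rank_results(df)
        assert list(ranked["category_id"]) == ["b", "a"]
        assert list(ranked["rank"]) == [1, 2]

    def test_ties_broken_by_observed_then_id(self):
        df = pd.DataFrame(
            {"category_id": ["c1", "c2", "c3"], "observed": [5, 9, 9], "p_value": [0.01, 0.01, 0.01]}
        )
        ranked = rank_results(df)
        assert list(ranked["category_id"]) == ["c2", "c3", "c1"]

    def test_single_category(self):
        df = pd.DataFrame({"category_id": ["only"], "observed": [1], "p_value": [0.5]})
        assert rank_results(df)["rank"].tolist() == [1]


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        out = bh_adjust(ps)
        assert np.all(out >= np.asarray(ps) - 1e-15)
        assert np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestFamilyFraction:
    def _family(self, n, name="TF:X"):
        return CategoryMap(name, name, "TF", frozenset(f"m{i}" for i in range(n)))

    @pytest.mark.parametrize("k,n,percent", [(9, 95, 9.5), (15, 107, 14.0), (0, 50, 0.0)])
    def test_percent_to_one_decimal(self, k, n, percent):
        fam = self._family(n)
        regulated = [f"m{i}" for i in range(k)]
        assert family_regulation_fraction(fam, regulated) == (k, n, percent)

    def test_report_ratio_rounding_per_namespace(self):
        df = pd.DataFrame(
            {
                "category_id": ["TF:WRKY", "TF:bZIP", "osa03010", "GO:0005840"],
                "label": ["WRKY", "bZIP", "Ribosome", "ribosome"],
                "namespace": ["TF", "TF", "KEGG", "GO"],
                "pathway_size": [107, 95, 362, 481],
                "observed": [15, 9, 57, 61],
                "ratio": [15 / 107, 9 / 95, 57 / 362, 61 / 481],
                "p_value": [1e-8, 1e-4, 1e-29, 1e-26],
                "rank": [1, 2, 3, 4],
            }
        )
        report = format_report(df, top=None)
        assert list(report["Ratio"]) == [0.14, 0.095, 0.16, 0.13]
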