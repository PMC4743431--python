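"""Audic-Claverie exact test, BH correction and DEG calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tagdge.de import (
    ac_probability,
    ac_two_sided_p,
    bh_fdr,
    call_degs,
    compare_deg_sets,
    comparison_summary,
    fold_change_distribution,
)
from tagdge.quantify import GeneExpressionTable


# --- independent arbitrary-precision oracle --------------------------------

def exact_pmf(y: int, x: int, ratio: Fraction) -> Fraction:
    """p(y|x) as an exact rational for a rational N2/N1."""
    return ratio**y * comb(x + y, y) / (1 + ratio) ** (x + y + 1)


def exact_two_sided(x: int, y: int, ratio: Fraction) -> Fraction:
    lower = sum(exact_pmf(k, x, ratio) for k in range(y + 1))
    upper = 1 - sum(exact_pmf(k, x, ratio) for k in range(y))
    return min(Fraction(1), 2 * min(lower, upper))


def make_expr(counts: dict[str, int], clean_total: int) -> GeneExpressionTable:
    table = pd.DataFrame(
        {"raw_count": pd.Series(counts, dtype=int)}
    )
    table["tpm"] = 1e6 * table["raw_count"] / clean_total
    table.index.name = "gene_id"
    return GeneExpressionTable(table, clean_total, len(table))


class TestAcProbability:
    def test_zero_zero_equal_libraries_is_half(self):
        assert ac_probability(0, 0, 1000, 1000) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("x", [0, 3, 17, 50])
    @pytest.mark.parametrize("n1,n2", [(1000, 1000), (1000, 2000), (3000, 1500)])
    def test_matches_exact_rational_oracle(self, x, n1, n2):
        ratio = Fraction(n2, n1)
        for y in [0, 1, 5, 20, 50]:
            expected = float(exact_pmf(y, x, ratio))
            assert ac_probability(y, x, n1, n2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("x", [0, 5, 50])
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_distribution_normalizes(self, x, ratio):
        n1, n2 = 10_000, int(10_000 * ratio)
        total, y = 0.0, 0
        while True:
            p = ac_probability(y, x, n1, n2)
            total += p
            if y > x and p < 1e-12:
                break
            y += 1
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_under_library_exchange(self):
        # exact pointwise symmetry holds for equal totals; in general the
        # exchanged pmf differs by the constant factor N1/N2
        for x, y in [(0, 0), (3, 8), (20, 5)]:
            assert ac_probability(y, x, 1000, 1000) == pytest.approx(
                ac_probability(x, y, 1000, 1000), rel=1e-12
            )
            assert ac_probability(y, x, 1000, 2500) == pytest.approx(
                (1000 / 2500) * ac_probability(x, y, 2500, 1000), rel=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            ac_two_sided_p(0, -2, 10, 10)

    def test_agrees_with_negative_binomial_form(self):
        # p(.|x) is NB(x+1, N1/(N1+N2)); scipy provides the cross-check
        n1, n2 = 1200, 800
        for x in [0, 4, 30]:
            ys = np.arange(0, 60)
            ours = [ac_probability(int(y), x, n1, n2) for y in ys]
            ref = sps.nbinom.pmf(ys, x + 1, n1 / (n1 + n2))
            assert np.allclose(ours, ref, atol=1e-13)


class TestTwoSidedP:
    def test_zero_zero_is_one(self):
        assert ac_two_sided_p(0, 0, 1000, 1000) == 1.0

    def test_strong_difference_is_small(self):
        assert ac_two_sided_p(0, 20, 1000, 1000) < 1e-4

    def test_equal_counts_is_large(self):
        assert ac_two_sided_p(100, 100, 1000, 1000) > 0.5

    @pytest.mark.parametrize("ratio", [Fraction(1, 2), Fraction(1), Fraction(2)])
    def test_matches_exact_oracle_on_grid(self, ratio):
        n1 = 10_000
        n2 = int(n1 * ratio)
        for x in [0, 2, 9, 27, 50]:
            for y in [0, 1, 6, 23, 50]:
                expected = float(exact_two_sided(x, y, ratio))
                assert ac_two_sided_p(x, y, n1, n2) == pytest.approx(
                    expected, abs=1e-10
                )

    def test_decreasing_in_departure_from_expectation(self):
        x, n1, n2 = 40, 5000, 5000
        ps = [ac_two_sided_p(x, y, n1, n2) for y in range(40, 120, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_extreme_tail_avoids_cancellation(self):
        p = ac_two_sided_p(0, 400, 10_000, 10_000)
        assert 0 < p < 1e-100

    def test_minlike_variant_is_a_valid_p_value(self):
        for x, y in [(3, 11), (0, 6), (25, 10)]:
            p_min = ac_two_sided_p(x, y, 1000, 1500, method="minlike")
            assert ac_probability(y, x, 1000, 1500) <= p_min <= 1.0
        assert ac_two_sided_p(0, 30, 1000, 1000, method="minlike") < 1e-6
        assert ac_two_sided_p(50, 50, 1000, 1000, method="minlike") > 0.5


class TestBhFdr:
    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_value_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_dominates_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()

    def test_matches_step_up_definition(self):
        """Independent hand implementation of the BH step-up rule."""
        rng = np.random.default_rng(1)
        p = rng.random(57)
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), expected)


class TestCallDegs:
    def test_four_fold_drop_called_down(self):
        e1 = make_expr({"G1": 200, "G2": 1000}, 100_000)
        e2 = make_expr({"G1": 50, "G2": 1000}, 100_000)
        recs = call_degs(e1, e2).set_index("gene_id")
        assert recs.at["G1", "log2_ratio"] == pytest.approx(-2.0)
        assert recs.at["G1", "fdr"] <= 0.001
        assert recs.at["G1", "status"] == "down"
        assert recs.at["G2", "status"] == "not_significant"

    def test_fold_change_without_significance_is_not_called(self):
        e1 = make_expr({"G1": 1, "G2": 500}, 100_000)
        e2 = make_expr({"G1": 8, "G2": 500}, 100_000)
        recs = call_degs(e1, e2).set_index("gene_id")
        assert recs.at["G1", "log2_ratio"] == pytest.approx(3.0)
        assert recs.at["G1", "fdr"] > 0.001
        assert recs.at["G1", "status"] == "not_significant"

    def test_significance_without_fold_change_is_not_called(self):
        e1 = make_expr({"G1": 20_000, "G2": 10}, 1_000_000)
        e2 = make_expr({"G1": 28_000, "G2": 10}, 1_000_000)
        recs = call_degs(e1, e2).set_index("gene_id")
        assert recs.at["G1", "fdr"] < 1e-6
        assert abs(recs.at["G1", "log2_ratio"]) < 1
        assert recs.at["G1", "status"] == "not_significant"

    def test_absent_genes_excluded_from_testing(self):
        e1 = make_expr({"G1": 5, "G2": 0}, 1000)
        e2 = make_expr({"G1": 5, "G2": 0}, 1000)
        recs = call_degs(e1, e2)
        assert list(recs["gene_id"]) == ["G1"]

    def test_single_library_zero_uses_pseudo_tpm(self):
        e1 = make_expr({"G1": 100, "G2": 100}, 100_000)
        e2 = make_expr({"G1": 0, "G2": 100}, 100_000)
        recs = call_degs(e1, e2).set_index("gene_id")
        assert np.isfinite(recs.at["G1", "log2_ratio"])
        assert recs.at["G1", "log2_ratio"] < -1

    def test_mismatched_universes_rejected(self):
        e1 = make_expr({"G1": 5}, 1000)
        e2 = make_expr({"G2": 5}, 1000)
        with pytest.raises(ValueError):
            call_degs(e1, e2)

    def test_label_exchange_flips_signs_and_swaps_calls(self):
        rng = np.random.default_rng(8)
        c1 = {f"G{i}": int(v) for i, v in enumerate(rng.poisson(60, size=300))}
        c2 = {g: int(v * (4 if i % 17 == 0 else 1)) for i, (g, v) in enumerate(c1.items())}
        e1 = make_expr(c1, 50_000)
        e2 = make_expr(c2, 55_000)
        fwd = call_degs(e1, e2).set_index("gene_id").sort_index()
        rev = call_degs(e2, e1).set_index("gene_id").sort_index()
        assert np.allclose(fwd["log2_ratio"], -rev["log2_ratio"])
        # the conditional test is not exactly exchange-symmetric; the two
        # directions agree within the tail-doubling factor
        ratio = fwd["p_value"] / rev["p_value"]
        assert ((ratio > 0.5 - 1e-9) & (ratio < 2.0 + 1e-9)).all()
        s_fwd = comparison_summary(fwd.reset_index())
        s_rev = comparison_summary(rev.reset_index())
        assert (s_fwd["n_up"], s_fwd["n_down"]) == (s_rev["n_down"], s_rev["n_up"])


class TestFoldChangeBins:
    def _records(self, fold_changes):
        return pd.DataFrame({"log2_ratio": np.log2(fold_changes)})

    def test_boundary_convention(self):
        bins = fold_change_distribution(self._records([4.9, 5.0, 1 / 5.0, 1.0]))
        assert bins["within_count"] == 2  # 4.9 and 1.0
        assert bins["up_count"] == 1  # 5.0 inclusive on the extreme bin
        assert bins["down_count"] == 1

    def test_percentages_sum_to_100(self):
        bins = fold_change_distribution(self._records([0.1, 0.5, 1, 2, 10]))
        assert bins["within_pct"] + bins["up_pct"] + bins["down_pct"] == pytest.approx(100)

    def test_boundary_must_exceed_one(self):
        with pytest.raises(ValueError):
            fold_change_distribution(self._records([1.0]), boundary=1.0)


class TestCompareDegSets:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"1", "2", "3"}, {"3", "4"}, (2, 1, 1)),
            ({"1"}, {"2"}, (1, 1, 0)),
            ({"1", "2"}, {"1", "2"}, (0, 0, 2)),
        ],
    )
    def test_partition_counts(self, a, b, expected):
        assert compare_deg_sets(a, b) == expected
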