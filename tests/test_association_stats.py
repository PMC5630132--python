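"""Exact 2x2 inference: Fisher tail, Woolf CI, burden counting."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from conftest import make_matrix
from geneburden.association_stats import (
    TwoByTwo,
    bonferroni,
    burden_counts,
    fisher_one_sided,
    gene_burden_test,
    odds_ratio_woolf,
    replay_table,
    single_variant_test,
)
from geneburden.errors import DegenerateDataError


def enumeration_oracle(a, n1, b, n2):
    """Upper-tail p by exhaustive enumeration of achievable tables,
    using exact integer binomial coefficients."""
    total = a + b
    if total == 0:
        return 1.0
    terms = [math.comb(n1, k) * math.comb(n2, total - k)
             for k in range(a, min(n1, total) + 1)
             if 0 <= total - k <= n2]
    return math.fsum(float(t) for t in terms) / float(math.comb(n1 + n2, total))


class TestFisherOneSided:
    @pytest.mark.parametrize("a,n1,b,n2,expected", [
        (26, 1886, 4, 1700, 8.6e-5),   # gene burden, strongest signal
        (10, 1860, 0, 1693, 1.5e-3),   # single variant, zero control carriers
        (23, 1886, 6, 1700, 2.7e-3),
        (114, 1886, 52, 1700, 1.2e-5),
        (7, 1883, 0, 1697, 1.1e-2),
    ])
    def test_published_style_tables_at_2_significant_figures(self, a, n1, b, n2, expected):
        p = fisher_one_sided(TwoByTwo(a, n1, b, n2))
        assert float(f"{p:.1e}") == pytest.approx(expected)

    def test_small_table_equals_exact_fraction(self):
        # enumeration by hand: margins (2, 10, 10) -> P(X >= 2) = 45/190
        assert fisher_one_sided(TwoByTwo(2, 10, 0, 10)) == pytest.approx(
            45 / 190, rel=1e-12)

    def test_empty_table_returns_one(self):
        assert fisher_one_sided(TwoByTwo(0, 10, 0, 10)) == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_and_scipy_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n1, n2 = int(rng.integers(1, 40)), int(rng.integers(1, 40))
            a, b = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            ours = fisher_one_sided(TwoByTwo(a, n1, b, n2))
            assert ours == pytest.approx(enumeration_oracle(a, n1, b, n2), rel=1e-12)
            scipy_p = fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="greater")[1]
            assert ours == pytest.approx(scipy_p, rel=1e-9)

    def test_monotone_decreasing_in_a_with_margins_fixed(self):
        n1, n2, total = 25, 30, 12
        ps = [fisher_one_sided(TwoByTwo(a, n1, total - a, n2))
              for a in range(total + 1)]
        assert all(hi > lo for hi, lo in zip(ps, ps[1:]))

    def test_invariants_rejected(self):
        with pytest.raises(DegenerateDataError):
            TwoByTwo(5, 4, 0, 10)
        with pytest.raises(DegenerateDataError):
            TwoByTwo(-1, 4, 0, 10)


class TestWoolfOddsRatio:
    @pytest.mark.parametrize("a,n1,b,n2,or_,lo,hi", [
        (23, 1886, 6, 1700, 3.49, 1.42, 8.58),
        (44, 1886, 16, 1700, 2.51, 1.41, 4.47),
        (114, 1886, 52, 1700, 2.04, 1.46, 2.85),
        (26, 1886, 4, 1700, 5.93, 2.06, 17.02),
        (16, 1886, 4, 1700, 3.63, 1.21, 10.87),
        (4, 1535, 4, 1235, 0.80, 0.20, 3.22),
    ])
    def test_published_style_tables_at_2_decimals(self, a, n1, b, n2, or_, lo, hi):
        est = odds_ratio_woolf(TwoByTwo(a, n1, b, n2))
        assert est is not None
        assert round(est[0], 2) == or_
        assert round(est[1], 2) == lo
        assert round(est[2], 2) == hi

    def test_equal_proportions_give_or_one(self):
        est = odds_ratio_woolf(TwoByTwo(10, 110, 10, 110))
        assert est[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        TwoByTwo(7, 1883, 0, 1697),  # zero control carriers
        TwoByTwo(0, 10, 3, 10),      # zero case carriers
        TwoByTwo(10, 10, 3, 10),     # zero case non-carriers
    ])
    def test_zero_cell_is_undefined(self, table):
        assert odds_ratio_woolf(table) is None

    def test_interval_symmetric_on_log_scale(self):
        or_, lo, hi = odds_ratio_woolf(TwoByTwo(12, 50, 5, 60))
        assert lo < or_ < hi
        assert math.log(or_) - math.log(lo) == pytest.approx(
            math.log(hi) - math.log(or_), rel=1e-9)

    def test_matches_direct_log_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = int(rng.integers(2, 200)), int(rng.integers(2, 200))
            a, b = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            est = odds_ratio_woolf(TwoByTwo(a, n1, b, n2))
            c, d = n1 - a, n2 - b
            orr = (a * d) / (b * c)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert est[0] == pytest.approx(orr, rel=1e-12)
            assert est[1] == pytest.approx(orr * math.exp(-1.959964 * se), rel=1e-9)
            assert est[2] == pytest.approx(orr * math.exp(+1.959964 * se), rel=1e-9)


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni(0.01, 9) == pytest.approx(0.09)
        assert bonferroni(0.2, 9) == 1.0
        assert bonferroni(0.03, 1) == 0.03

    def test_nine_gene_correction_of_strongest_signal(self):
        p = fisher_one_sided(TwoByTwo(26, 1886, 4, 1700))
        assert f"{bonferroni(p, 9):.0e}" == "8e-04"

    def test_threshold_for_nine_genes(self):
        # 0.0061 fails the 0.05/9 = 0.0055 family-wise threshold
        assert not (0.0061 <= 0.05 / 9)
        assert 0.0027 <= 0.05 / 9


class TestBurdenCounting:
    def _matrix(self):
        # cases: S0 het at site0; S1 het at site1 and site2; S2 hom at site0;
        # S3-S5 non-carriers. controls: S6 het at site3 (non-qualifying),
        # S7, S8 non-carriers
        calls = [
            [1, 0, 0, 0],
            [0, 1, 1, 0],
            [2, 0, 0, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 1],
            [0, 0, 0, 0],
            [0, 0, 0, 0],
        ]
        return make_matrix(calls, ["case"] * 6 + ["control"] * 3)

    def test_per_site_rule_counts_sample_site_pairs(self):
        matrix = self._matrix()
        qualifying = matrix.sites[:3]
        t = burden_counts(matrix, qualifying)
        # S0: 1, S1: 2 (two qualifying sites), S2: 1 (homozygote counts once)
        assert (t.a, t.n1, t.b, t.n2) == (4, 6, 0, 3)

    def test_alleles_rule_counts_copies(self):
        t = burden_counts(self._matrix(), self._matrix().sites[:3],
                          count_rule="alleles")
        assert t.a == 5  # homozygote contributes 2

    def test_per_sample_rule_collapses_carriers(self):
        t = burden_counts(self._matrix(), self._matrix().sites[:3],
                          count_rule="per_sample")
        assert t.a == 3

    def test_empty_qualifying_set_gives_null_table(self):
        t = burden_counts(self._matrix(), [])
        assert (t.a, t.b) == (0, 0)
        assert fisher_one_sided(t) == 1.0

    def test_result_invariant_to_sample_and_site_order(self):
        matrix = self._matrix()
        qualifying = matrix.sites[:3]
        base = gene_burden_test(matrix, qualifying, "G")
        perm_samples = matrix.subset_samples(np.array([5, 2, 0, 8, 4, 1, 6, 3, 7]))
        perm_sites = matrix.subset_sites(np.array([3, 1, 0, 2]))
        assert gene_burden_test(perm_samples, qualifying, "G").table == base.table
        assert gene_burden_test(perm_sites, qualifying, "G").table == base.table

    def test_count_exceeding_group_size_is_rejected(self):
        # 1 case carrying three qualifying variants: the per-pair rule would
        # yield a = 3 > n1 = 1, which violates the 2x2 invariants
        matrix = make_matrix([[1, 1, 1], [0, 0, 0]], ["case", "control"])
        with pytest.raises(DegenerateDataError, match="margin"):
            burden_counts(matrix, matrix.sites)


class TestSingleVariant:
    def test_per_site_denominators_exclude_missing(self):
        calls = [
            [1, 0],
            [-1, 0],
            [0, 0],
            [0, -1],
            [1, 0],
            [0, 0],
        ]
        matrix = make_matrix(calls, ["case"] * 3 + ["control"] * 3)
        r = single_variant_test(matrix, matrix.sites[0])
        # case S1 is uncalled at site0 -> n1 = 2; control carrier S4
        assert (r.table.a, r.table.n1, r.table.b, r.table.n2) == (1, 2, 1, 3)

    def test_monomorphic_site_gives_p_one(self):
        calls = np.zeros((4, 1), dtype=np.int8)
        matrix = make_matrix(calls, ["case", "case", "control", "control"])
        r = single_variant_test(matrix, matrix.sites[0])
        assert r.p_one_sided == 1.0
        assert r.odds_ratio is None


class TestReplayBatch:
    def test_replay_reproduces_published_burden_row(self):
        (r,) = replay_table([("CASP8", 26, 1886, 4, 1700)], m=9)
        assert float(f"{r.p_one_sided:.1e}") == pytest.approx(8.6e-5)
        assert round(r.odds_ratio, 2) == 5.93
        assert float(f"{r.p_bonferroni:.1e}") == pytest.approx(7.7e-4)

    def test_replay_accepts_dict_rows(self):
        (r,) = replay_table([{"label": "x", "a": 2, "n1": 10, "b": 0, "n2": 10}])
        assert r.p_one_sided == pytest.approx(45 / 190, rel=1e-12)
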