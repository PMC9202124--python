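"""Cohort statistics: Fisher oracle, BH, rank-sum, log-rank, co-occurrence."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from melscape.drivers import AlterationEvent, build_alteration_matrix
from melscape.stats import (
    SurvivalRecord,
    bh_adjust,
    compare_group_frequencies,
    cooccurrence_scan,
    count_interregion_junctions,
    fisher_exact_2x2,
    kaplan_meier,
    linked_samples,
    logrank_test,
    mutation_burden,
    rank_sum_test,
)


def fisher_oracle(a, b, c, d, slack=1e-7):
    """Independent enumeration over the hypergeometric support."""
    n1, n2, m = a + b, c + d, a + c
    lo, hi = max(0, m - n2), min(m, n1)
    p_obs = hypergeom.pmf(a, n1 + n2, n1, m)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom.pmf(x, n1 + n2, n1, m)
        if p <= p_obs * (1 + slack):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_diagonal_table_enumeration(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-9)

    def test_cohort_scale_table(self):
        assert fisher_exact_2x2(12, 81, 0, 147) == pytest.approx(7.2258e-6, rel=1e-4)

    def test_empty_margin(self):
        assert fisher_exact_2x2(0, 0, 3, 5) == 1.0

    def test_agrees_with_enumeration_oracle(self):
        """Sweep of tables with N <= 26 against full-support enumeration."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 14, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-6, abs=1e-12
            )


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_textbook_example(self):
        assert bh_adjust([0.001, 0.02, 0.03]) == pytest.approx([0.003, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRankSum:
    def test_identical_groups(self):
        assert rank_sum_test([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_exact_small_sample(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_power_under_shift(self, rng):
        """1-SD shift at n=50/50 rejected in > 80% of simulations."""
        rejections = 0
        for _ in range(200):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            rejections += rank_sum_test(a, b) < 0.05
        assert rejections / 200 > 0.80


class TestSurvival:
    def records(self, times1, events1, times2, events2):
        recs = [SurvivalRecord(f"a{i}", t, bool(e), "g1") for i, (t, e) in enumerate(zip(times1, events1))]
        recs += [SurvivalRecord(f"b{i}", t, bool(e), "g2") for i, (t, e) in enumerate(zip(times2, events2))]
        return recs

    def test_identical_groups_null(self):
        recs = self.records([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        chi2, p = logrank_test(recs)
        assert chi2 == pytest.approx(0.0, abs=1e-9) and p == pytest.approx(1.0)

    def test_hand_computed_separation(self):
        """5 events at t=1 in group 1 vs 5 censored at t=2 in group 2.

        Single event time t=1: d=5, n=10, per-event E1 = 5/10, V per event =
        (n1 n2 d (n-d)) / (n^2 (n-1)) summed via hypergeometric increments;
        O1-E1 = 5 - 2.5 = 2.5, V = 5 * (5*5*(10-1)... ) -> chi2 = 2.5^2 / V.
        """
        recs = self.records([1] * 5, [1] * 5, [2] * 5, [0] * 5)
        chi2, p = logrank_test(recs)
        # hand evaluation: events processed at one time with d=5:
        # E1 = d*n1/n = 2.5; V1 = d*(n1/n)*(1-n1/n)*(n-d)/(n-1) = 5*.25*5/9
        v = 5 * 0.25 * 5 / 9
        assert chi2 == pytest.approx(2.5 ** 2 / v, rel=1e-6)
        assert p < 0.05

    def test_no_subjects_in_group_error(self):
        with pytest.raises(ValueError):
            logrank_test([SurvivalRecord("a", 1, True, "g1")])

    def test_km_product_form(self):
        recs = [SurvivalRecord(f"s{i}", t, True, "g") for i, t in enumerate([1, 2, 3, 4])]
        km = kaplan_meier(recs)
        # S(t) after k-th of 4 distinct events = prod (1 - 1/n_i)
        final = km["survival"].iloc[-1]
        assert final == pytest.approx(0.0, abs=1e-12)
        s_at_2 = km.loc[km["time"] == 2, "survival"].iloc[0]
        assert s_at_2 == pytest.approx((1 - 1 / 4) * (1 - 1 / 3))


def matrix_from_bool(df: pd.DataFrame, arms=None, categories=None):
    events = []
    for sid, row in df.iterrows():
        for grp, v in row.items():
            if v:
                gene = grp.split("_")[0]
                cat = categories.get(grp, "oncogene_mutation") if categories else "oncogene_mutation"
                events.append(AlterationEvent(sid, gene, cat))
    return build_alteration_matrix(
        events, samples=list(df.index), gene_arms=arms or {}, min_count=1
    )


class TestFrequencyComparison:
    def test_subtype_exclusive_group(self):
        """12/93 vs 0/147 as the smallest of 35 tests adjusts to ~2.5e-4."""
        n_a, n_b = 147, 93
        samples = [f"s{i}" for i in range(n_a + n_b)]
        occ = pd.DataFrame(0, index=samples, columns=[f"G{j}_mutation" for j in range(1)])
        occ.iloc[n_a : n_a + 12, 0] = 1
        m = matrix_from_bool(occ)
        labels = pd.Series(["acral"] * n_a + ["mucosal"] * n_b, index=samples)
        res = compare_group_frequencies(m, labels)[0]
        assert res.p_value == pytest.approx(7.2258e-6, rel=1e-4)
        # smallest of 35 tests: BH multiplies by 35
        assert 35 * res.p_value == pytest.approx(0.000253, rel=0.02)

    def test_identical_frequencies_p_one(self):
        samples = [f"s{i}" for i in range(40)]
        occ = pd.DataFrame(0, index=samples, columns=["G_mutation"])
        occ.iloc[:5, 0] = 1
        occ.iloc[20:25, 0] = 1
        labels = pd.Series(["x"] * 20 + ["y"] * 20, index=samples)
        res = compare_group_frequencies(matrix_from_bool(occ), labels)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_partition_rejected(self):
        samples = ["a", "b"]
        occ = pd.DataFrame([[1], [0]], index=samples, columns=["G_mutation"])
        labels = pd.Series(["x", "x"], index=samples)
        with pytest.raises(ValueError):
            compare_group_frequencies(matrix_from_bool(occ), labels)


class TestCooccurrence:
    def test_perfect_overlap_small(self):
        samples = [f"s{i}" for i in range(10)]
        occ = pd.DataFrame(0, index=samples, columns=["A_mutation", "B_mutation"])
        occ.iloc[:5] = 1
        res = cooccurrence_scan(matrix_from_bool(occ))
        r = res[0]
        assert r.p_value == pytest.approx(2 / 252, rel=1e-9)
        # o=5, e=2.5 -> log2(5.5/3.0)
        assert r.effect_log2 == pytest.approx(math.log2(5.5 / 3.0))

    def test_same_arm_amplifications_excluded(self):
        samples = [f"s{i}" for i in range(12)]
        occ = pd.DataFrame(1, index=samples, columns=["CCND1_amplification", "PAK1_amplification"])
        m = matrix_from_bool(
            occ,
            arms={"CCND1": "11q", "PAK1": "11q"},
            categories={c: "oncogene_amplification" for c in occ.columns},
        )
        res = cooccurrence_scan(m)
        assert res[0].excluded and res[0].excluded_reason == "same_arm"
        assert res[0].p_value is None

    def test_different_arm_amplifications_tested(self):
        samples = [f"s{i}" for i in range(12)]
        occ = pd.DataFrame(1, index=samples, columns=["CCND1_amplification", "CDK4_amplification"])
        m = matrix_from_bool(
            occ,
            arms={"CCND1": "11q", "CDK4": "12q"},
            categories={c: "oncogene_amplification" for c in occ.columns},
        )
        assert cooccurrence_scan(m)[0].p_value is not None

    def test_symmetric_under_sample_permutation(self, rng):
        samples = [f"s{i}" for i in range(30)]
        occ = pd.DataFrame(
            rng.integers(0, 2, size=(30, 3)), index=samples,
            columns=["A_mutation", "B_mutation", "C_mutation"],
        )
        res1 = cooccurrence_scan(matrix_from_bool(occ))
        perm = rng.permutation(30)
        res2 = cooccurrence_scan(matrix_from_bool(occ.iloc[perm]))
        for r1, r2 in zip(res1, res2):
            assert r1.p_value == pytest.approx(r2.p_value)
            assert (r1.a, r1.b, r1.c, r1.d) == (r2.a, r2.b, r2.c, r2.d)


class TestBurdenAndJunctions:
    def test_burden_simple(self):
        assert mutation_burden(100, 50) == 2.0
        assert mutation_burden(0, 50) == 0.0
        with pytest.raises(ValueError):
            mutation_burden(5, 0)

    def junctions(self):
        return pd.DataFrame(
            [
                {"sample_id": "s1", "chrom1": "chr6", "start1": 64_000_000, "end1": 64_000_001,
                 "chrom2": "chr11", "start2": 70_000_000, "end2": 70_000_001},
                {"sample_id": "s1", "chrom1": "chr11", "start1": 75_000_000, "end1": 75_000_001,
                 "chrom2": "chr6", "start2": 63_500_000, "end2": 63_500_001},
                {"sample_id": "s1", "chrom1": "chr6", "start1": 63_000_000, "end1": 63_000_001,
                 "chrom2": "chr6", "start2": 64_500_000, "end2": 64_500_001},
                {"sample_id": "s2", "chrom1": "chr2", "start1": 1000, "end1": 1001,
                 "chrom2": "chr3", "start2": 2000, "end2": 2001},
            ]
        )

    def test_cross_region_counting(self):
        region6 = ("chr6", 62_000_000, 66_000_000)
        region11 = ("chr11", 68_000_000, 79_000_000)
        counts = count_interregion_junctions(self.junctions(), region6, region11)
        # both orientations count; the intra-chr6 junction does not
        assert counts.to_dict() == {"s1": 2}
        assert linked_samples(self.junctions(), region6, region11) == ["s1"]

    def test_planted_cross_region_recovered(self, small_cohort):
        cfg, bundle, truth = small_cohort
        region6 = ("chr6", 63_000_000, 65_000_000)
        region11 = ("chr11", 68_000_000, 79_000_000)
        counts = count_interregion_junctions(bundle.junctions, region6, region11)
        for r in truth.cross_region_junctions.to_dict("records"):
            if r["n_planted"]:
                assert counts.get(r["sample_id"], 0) >= r["n_planted"]
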