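"""Diversity, dominance, and representativeness statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonosim import (
    CloneProfile,
    StatsConfig,
    biomass_captured,
    dominant_clones,
    group_comparison,
    partition_center_periphery,
    pct_barcodes_detected,
    representativeness,
    sample_tumor_correlation,
    shannon_index,
)

TUMOR = CloneProfile("tumor", {1: 70, 2: 20, 3: 10})

profile_strategy = st.dictionaries(
    st.integers(min_value=1, max_value=50),
    st.floats(min_value=0.01, max_value=100, allow_nan=False),
    min_size=1,
    max_size=20,
)


class TestShannon:
    def test_uniform_is_log_n(self):
        p = CloneProfile("u", {i: 1 for i in range(4)})
        assert shannon_index(p) == pytest.approx(math.log(4), abs=1e-12)

    def test_singleton_is_zero(self):
        assert shannon_index(CloneProfile("s", {1: 99})) == 0.0

    def test_half_quarter_quarter(self):
        p = CloneProfile("p", {1: 2, 2: 1, 3: 1})
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon_index(p) == pytest.approx(expected, abs=1e-12)
        assert shannon_index(p) == pytest.approx(1.0397, abs=1e-4)

    def test_base_two_option(self):
        p = CloneProfile("u", {1: 1, 2: 1})
        assert shannon_index(p, base=2) == pytest.approx(1.0, abs=1e-12)

    def test_empty_profile_convention(self):
        assert shannon_index(CloneProfile("e", {})) == 0.0

    @given(profile_strategy)
    def test_bounded_by_log_richness(self, counts):
        p = CloneProfile("h", counts)
        h = shannon_index(p)
        assert -1e-9 <= h <= math.log(p.richness) + 1e-9


class TestDetection:
    def test_full_detection(self):
        assert pct_barcodes_detected(TUMOR, TUMOR) == 100.0

    def test_empty_sample(self):
        assert pct_barcodes_detected(CloneProfile("e", {}), TUMOR) == 0.0

    def test_partial(self):
        sample = CloneProfile("s", {1: 5, 3: 5})
        assert pct_barcodes_detected(sample, TUMOR) == pytest.approx(66.67, abs=0.01)

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError):
            pct_barcodes_detected(TUMOR, CloneProfile("e", {}))


class TestBiomass:
    def test_full_coverage(self):
        assert biomass_captured(TUMOR, TUMOR) == pytest.approx(100.0)

    def test_partial_sum_of_tumor_frequencies(self):
        sample = CloneProfile("s", {1: 1, 3: 1})
        assert biomass_captured(sample, TUMOR) == pytest.approx(80.0)

    def test_monotone_under_union(self):
        s1 = CloneProfile("s1", {1: 1})
        s2 = CloneProfile("s2", {2: 1})
        joint = biomass_captured([s1, s2], TUMOR)
        assert joint >= biomass_captured(s1, TUMOR)
        assert joint >= biomass_captured(s2, TUMOR)
        assert joint == pytest.approx(90.0)

    def test_foreign_barcodes_contribute_nothing(self):
        sample = CloneProfile("s", {99: 10})
        assert biomass_captured(sample, TUMOR) == 0.0


class TestDominance:
    def test_strictly_greater_than_one_percent(self):
        p = CloneProfile("p", {1: 10_000 - 101 - 100, 2: 101, 3: 100})
        dom = dominant_clones(p)
        assert 2 in dom  # 1.01%
        assert 3 not in dom  # exactly 1.00%

    def test_uniform_200_clones_has_no_dominants(self):
        p = CloneProfile("u", {i: 1 for i in range(200)})
        assert dominant_clones(p) == frozenset()

    def test_two_clone_tumor(self):
        p = CloneProfile("p", {1: 98, 2: 2})
        assert dominant_clones(p) == {1, 2}

    def test_count_bounded_by_inverse_threshold(self):
        cfg = StatsConfig(dominance_threshold=0.05)
        p = CloneProfile("p", {i: 1 for i in range(100)})
        assert len(dominant_clones(p, cfg)) <= 20


class TestPartition:
    def test_identical_sets(self):
        center = CloneProfile("c", {1: 1, 2: 1})
        peri = [CloneProfile("p", {1: 2, 2: 2})]
        assert partition_center_periphery(center, peri) == (0.0, 0.0, 100.0)

    def test_disjoint_sets(self):
        center = CloneProfile("c", {9: 1})
        peri = [CloneProfile("p", {1: 1, 2: 1, 3: 1})]
        assert partition_center_periphery(center, peri) == (75.0, 25.0, 0.0)

    @given(
        st.sets(st.integers(1, 30), min_size=1, max_size=15),
        st.sets(st.integers(1, 30), min_size=1, max_size=15),
    )
    def test_percentages_sum_to_100(self, center_set, peri_set):
        center = CloneProfile("c", {b: 1 for b in center_set})
        peri = [CloneProfile("p", {b: 1 for b in peri_set})]
        parts = partition_center_periphery(center, peri)
        assert sum(parts) == pytest.approx(100.0, abs=1e-9)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            partition_center_periphery(
                CloneProfile("c", {}), [CloneProfile("p", {})]
            )


class TestCorrelation:
    def test_identical_profiles(self):
        assert sample_tumor_correlation(TUMOR, TUMOR) == pytest.approx(1.0)

    def test_reversed_two_clone_ranking(self):
        tumor = CloneProfile("t", {1: 70, 2: 30})
        sample = CloneProfile("s", {1: 30, 2: 70})
        assert sample_tumor_correlation(sample, tumor) == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        tumor = CloneProfile("t", {1: 40, 2: 30, 3: 20, 4: 10})
        sample = CloneProfile("s", {1: 10, 2: 10, 4: 30})
        barcodes = sorted(tumor.barcodes | sample.barcodes)
        x = np.array([sample.frequency(b) for b in barcodes])
        y = np.array([tumor.frequency(b) for b in barcodes])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert sample_tumor_correlation(sample, tumor) == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate_flagged_not_zero(self):
        tumor = CloneProfile("t", {1: 1, 2: 1})  # zero variance over union
        sample = CloneProfile("s", {1: 1, 2: 1})
        with pytest.warns(UserWarning):
            r = sample_tumor_correlation(sample, tumor)
        assert math.isnan(r)


class TestRepresentativeness:
    def test_bundles_metrics_and_missed_dominants(self):
        sample = CloneProfile("needle", {1: 5})
        res = representativeness(sample, TUMOR)
        assert res.pct_barcodes_detected == pytest.approx(100 / 3)
        assert res.pct_biomass_captured == pytest.approx(70.0)
        assert res.missed_dominant == {2, 3}

    def test_combination_increases_coverage(self):
        s1 = CloneProfile("needle", {1: 5})
        s2 = CloneProfile("cfdna", {2: 5})
        res = representativeness([s1, s2], TUMOR)
        assert res.pct_biomass_captured == pytest.approx(90.0)


class TestGroupComparison:
    def test_identical_groups_p_near_one(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        res = group_comparison(values, labels)
        assert res.method == "unpaired_t"
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        values = [0.0, 0.01, -0.01, 5.0, 5.01, 4.99]
        labels = ["a"] * 3 + ["b"] * 3
        res = group_comparison(values, labels)
        assert res.p_value < 0.001

    def test_three_groups_run_anova_tukey(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(0, 1, 5), rng.normal(0, 1, 5), rng.normal(8, 1, 5)]
        )
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = group_comparison(values, labels)
        assert res.method == "anova_tukey"
        assert res.p_value < 1e-4
        pairs = res.pairwise.set_index(["group1", "group2"])
        assert bool(pairs.loc[("a", "c"), "reject"])
        assert not bool(pairs.loc[("a", "b"), "reject"])

    def test_matches_textbook_t_formula(self):
        """Cross-check the two-group path against the pooled-variance t
        statistic computed by hand on a frozen fixture."""
        from scipy.stats import t as t_dist

        a = np.array([3.1, 2.9, 3.4, 3.0])
        b = np.array([3.8, 4.1, 3.9, 4.4])
        res = group_comparison(
            np.concatenate([a, b]), ["a"] * 4 + ["b"] * 4
        )
        sp2 = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / (len(a) + len(b) - 2)
        t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_manual = 2 * t_dist.sf(abs(t_stat), len(a) + len(b) - 2)
        assert res.statistic == pytest.approx(t_stat, abs=1e-10)
        assert res.p_value == pytest.approx(p_manual, abs=1e-10)

    def test_small_groups_not_determined(self):
        res = group_comparison([1.0, 2.0, 5.0, 6.0], ["a", "a", "b", "b"])
        assert not res.determined
        assert math.isnan(res.p_value)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison([1.0, 2.0], ["a", "a"])
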