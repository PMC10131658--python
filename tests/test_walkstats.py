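"""Misclassification statistics: proportions, Fisher tests, quartiles, t tests."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from walkanchor import (
    UsageError,
    avm_cov,
    bonferroni,
    clinical_threshold,
    cohort_report,
    fisher_active_test,
    intensity_distribution,
    pooled_t,
    quartile_groups,
)
from walkanchor.walkstats import ParticipantWalkSummary


class TestIntensityDistribution:
    # printed per-case and pooled epoch counts and their percentages
    @pytest.mark.parametrize(
        "counts, pct_sed",
        [
            ((253, 0, 1801), 12.3),       # moderate-arm-swing case, 253/2054
            ((277, 0, 285), 49.3),        # gait-aid case, 277/562
            ((867, 0, 680), 56.0),        # tremor case, 867/1547
        ],
    )
    def test_case_percentages(self, counts, pct_sed):
        sed, _, _ = intensity_distribution(*counts)
        assert round(sed, 1) == pct_sed

    def test_pooled_percentages(self):
        sed, light, mvpa = intensity_distribution(7446, 8861, 19941)
        assert round(sed, 2) == 20.54
        assert round(light, 2) == 24.45
        assert round(mvpa, 2) == 55.01

    def test_all_mvpa(self):
        assert intensity_distribution(0, 0, 50) == (0.0, 0.0, 100.0)

    def test_zero_total_flagged(self):
        with pytest.raises(UsageError):
            intensity_distribution(0, 0, 0)


def fisher_oracle(n_active, n_sedentary):
    """Full hypergeometric enumeration for the observed-vs-all-active table."""
    n = n_active + n_sedentary
    N, K = 2 * n, n_active + n  # grand total, active column total
    probs = [
        comb(n, x) * comb(n, K - x) / comb(N, K)
        for x in range(max(0, K - n), min(n, K) + 1)
    ]
    p_obs = comb(n, n_active) * comb(n, K - n_active) / comb(N, K)
    return sum(p for p in probs if p <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_no_sedentary_gives_p_one(self):
        assert fisher_active_test(40, 0) == 1.0

    def test_three_one_enumeration(self):
        # margins (4,4)x(7,1): only two admissible tables, each p=1/2
        assert fisher_active_test(3, 1) == pytest.approx(1.0)

    @pytest.mark.parametrize("active, sed", [(1774, 31), (680, 867)])
    def test_extreme_participants_below_point_001(self, active, sed):
        p = fisher_active_test(active, sed)
        assert p < 0.001
        assert bonferroni([p], 35)[0] < 0.001  # survives the family correction

    def test_matches_enumeration_for_small_totals(self):
        for a in range(0, 26):
            for s in range(0, 26 - a):
                if a + s == 0:
                    continue
                assert fisher_active_test(a, s) == pytest.approx(
                    fisher_oracle(a, s), rel=1e-9
                )

    def test_monotone_in_sedentary_count(self):
        total = 40
        ps = [fisher_active_test(total - s, s) for s in range(total + 1)]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestBonferroni:
    def test_simple_product(self):
        assert bonferroni([0.01], 35)[0] == pytest.approx(0.35)

    def test_capped_at_one(self):
        assert bonferroni([0.5], 35)[0] == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = bonferroni(ps, len(ps))
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(UsageError):
            bonferroni([0.1, 0.2], 1)


class TestClinicalThreshold:
    def test_boundary_inclusive(self):
        minutes, exceeds = clinical_threshold(80)
        assert minutes == 20.0 and exceeds

    def test_just_below(self):
        minutes, exceeds = clinical_threshold(79)
        assert minutes == 19.75 and not exceeds

    def test_tremor_case_count(self):
        minutes, exceeds = clinical_threshold(867)
        assert minutes == 216.75 and exceeds


class TestAvmCov:
    def test_constant_series_zero(self):
        assert avm_cov([42.0] * 10) == 0.0

    def test_simple_values(self):
        assert avm_cov([10.0, 20.0, 30.0]) == pytest.approx(50.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(23)
        x = rng.gamma(4, 25, size=400)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert avm_cov(x) == pytest.approx(sd / mean * 100, abs=1e-9)

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(UsageError):
            avm_cov([5.0])
        with pytest.raises(UsageError):
            avm_cov([0.0, 0.0])


class TestQuartiles:
    def test_35_participants_give_groups_of_9(self):
        vals = {f"p{i:02d}": float(i) for i in range(35)}
        q1, q4 = quartile_groups(vals)
        assert len(q1) == len(q4) == 9
        assert q1 == [f"p{i:02d}" for i in range(9)]
        assert q4 == [f"p{i:02d}" for i in range(26, 35)]

    def test_8_participants_give_groups_of_2(self):
        vals = {f"p{i}": float(i) for i in range(8)}
        q1, q4 = quartile_groups(vals)
        assert len(q1) == len(q4) == 2

    def test_boundary_ties_resolved_by_id(self):
        vals = {"a": 1.0, "b": 5.0, "c": 5.0, "d": 5.0, "e": 9.0, "f": 0.5}
        q1a, q4a = quartile_groups(vals)
        q1b, q4b = quartile_groups(dict(reversed(list(vals.items()))))
        assert (q1a, q4a) == (q1b, q4b)


class TestPooledT:
    # group summary rows recomputable from printed means/SDs at n=9 per group
    @pytest.mark.parametrize(
        "g1, g2, expect_t",
        [
            ((37.5, 16.9, 9), (51.2, 9.4, 9), 2.13),    # AVM CoV (%)
            ((112.8, 10.7, 9), (105.8, 12.7, 9), 1.26),  # median cadence
            ((338.5, 156.1, 9), (218.9, 86.0, 9), 2.01), # LONG-walk minutes
        ],
    )
    def test_printed_group_rows(self, g1, g2, expect_t):
        t, df, p = pooled_t(*g1, *g2)
        assert round(abs(t), 2) == expect_t
        assert df == 16

    def test_identical_groups(self):
        t, df, p = pooled_t(5.0, 1.0, 9, 5.0, 1.0, 9)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        t, df, p = pooled_t(5.0, 0.0, 5, 4.0, 0.0, 5)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_agrees_with_scipy(self):
        res = stats.ttest_ind_from_stats(37.5, 16.9, 9, 51.2, 9.4, 9)
        t, df, p = pooled_t(37.5, 16.9, 9, 51.2, 9.4, 9)
        assert t == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)


def make_summary(pid, n_sed, n_light, n_mvpa, cov=40.0, cadence=105.0):
    pct = intensity_distribution(n_sed, n_light, n_mvpa)
    minutes, exceeds = clinical_threshold(n_sed)
    return ParticipantWalkSummary(
        participant_id=pid,
        n_long_walks=10,
        long_walk_minutes=(n_sed + n_light + n_mvpa) * 0.25,
        median_cadence_spm=cadence,
        n_sedentary=n_sed,
        n_light=n_light,
        n_mvpa=n_mvpa,
        pct_sedentary=pct[0],
        pct_light=pct[1],
        pct_mvpa=pct[2],
        sedentary_misclassified_min=minutes,
        exceeds_clinical_threshold=exceeds,
        avm_cov_pct=cov,
        fisher_p=fisher_active_test(n_light + n_mvpa, n_sed),
    )


class TestCohortReport:
    def _cohort(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            n_sed = int(rng.integers(60, 900))
            out.append(
                make_summary(
                    f"p{i:02d}", n_sed, int(rng.integers(50, 400)),
                    int(rng.integers(100, 1200)), cov=float(rng.uniform(20, 70)),
                )
            )
        return out

    def test_row_count_and_shapes(self, tmp_path):
        table, comparisons = cohort_report(self._cohort(12), tmp_path)
        assert len(table) == 12
        assert (tmp_path / "participant_summary.csv").exists()
        assert (tmp_path / "quartile_comparisons.csv").exists()
        assert set(comparisons["variable"]) >= {"avm_cov_pct", "median_cadence_spm"}

    def test_threshold_fraction(self):
        # 10 of 12 designed to exceed the 20-min (80-epoch) threshold
        summaries = [
            make_summary(f"p{i:02d}", 200 if i < 10 else 40, 100, 400)
            for i in range(12)
        ]
        table, _ = cohort_report(summaries)
        assert table.attrs["n_exceeding_clinical_threshold"] == 10
        assert table.attrs["pct_exceeding_clinical_threshold"] == pytest.approx(83.3, abs=0.05)

    def test_quartile_groups_disjoint_and_bonferroni_filled(self):
        table, comparisons = cohort_report(self._cohort(12, seed=5))
        assert not set(comparisons.attrs["sed_q1"]) & set(comparisons.attrs["sed_q4"])
        np.testing.assert_allclose(
            table["fisher_p_bonferroni"],
            np.minimum(1.0, table["fisher_p"] * len(table)),
        )
        # percentages per participant sum to 100
        sums = table[["pct_sedentary", "pct_light", "pct_mvpa"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=0.1)
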