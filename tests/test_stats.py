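"""Nonparametric tests, FDR, bootstrap, correlations, summary t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import brute_force_bh_mask, exact_ranksum_p
from neurocrit.stats import (StatConfig, bh_fdr, bootstrap_ci, kruskal_wallis,
                             pairwise_wilcoxon, percent_significant, run_stat_battery,
                             spearman_corr, ttest_from_summary)


class TestKruskalWallis:
    def test_hand_computed_toy(self):
        h, p, eta2 = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)
        assert eta2 == pytest.approx((7.2 - 2) / 6)

    def test_identical_groups(self):
        h, p, eta2 = kruskal_wallis([5, 5], [5, 5], [5, 5])
        assert (h, p, eta2) == (0.0, 1.0, 0.0)

    def test_two_groups_consistent_with_ranksum(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        _, p_kw, _ = kruskal_wallis(a, b)
        _, p_w, _ = pairwise_wilcoxon(a, b)
        assert p_kw == pytest.approx(p_w, rel=0.05)

    def test_eta_squared_bounds(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.normal(), 1, 15) for _ in range(3)]
            h, _, eta2 = kruskal_wallis(*groups)
            if h >= 2:  # k - 1
                assert 0.0 <= eta2 <= 1.0


class TestWilcoxon:
    def test_identical_paired_samples(self):
        _, p, r = pairwise_wilcoxon([1, 2, 3], [1, 2, 3], paired=True)
        assert p == 1.0
        assert r == 0.0

    def test_extreme_arrangement_exact_p(self):
        _, p, _ = pairwise_wilcoxon([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_exact_p_matches_enumeration_small_n(self, rng):
        for trial in range(12):
            n1, n2 = rng.integers(3, 8), rng.integers(3, 8)
            a = rng.normal(0, 1, n1).round(2)
            b = rng.normal(0.5, 1, n2).round(2)
            if len(np.unique(np.concatenate([a, b]))) < n1 + n2:
                continue  # enumeration oracle assumes no cross-ties here
            _, p, _ = pairwise_wilcoxon(a, b)
            assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-9)

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (1000, 50))
        b = rng.normal(1, 1, (1000, 50))
        res = sps.mannwhitneyu(a, b, alternative="two-sided", axis=1)
        assert np.mean(res.pvalue < 0.05) > 0.9

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon([1, 2], [1, 2, 3], paired=True)

    def test_type_one_error_calibrated(self):
        # 10,000 null simulations, n = 30 per group, alpha = 0.05
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10_000, 30))
        b = rng.normal(size=(10_000, 30))
        res = sps.mannwhitneyu(a, b, alternative="two-sided", axis=1)
        rate = np.mean(res.pvalue < 0.05)
        assert 0.04 <= rate <= 0.06


class TestBH:
    def test_worked_example(self):
        adj, mask = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_empty_and_degenerate(self):
        adj, mask = bh_fdr([], q=0.1)
        assert adj.size == mask.size == 0
        adj, mask = bh_fdr([0.0, 0.0, 0.0], q=0.05)
        assert np.all(mask) and np.all(adj == 0)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=200)
        adj, _ = bh_fdr(p, q=0.1)
        assert np.all(adj >= p - 1e-12)

    def test_mask_matches_brute_force_step_up(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            q = rng.uniform(0.01, 0.3)
            _, mask = bh_fdr(p, q)
            np.testing.assert_array_equal(mask, brute_force_bh_mask(p, q))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2], q=0.05)


class TestBootstrap:
    def test_constant_vector_degenerate(self):
        assert bootstrap_ci(np.full(10, 3.5), seed=0) == (3.5, 3.5)

    def test_width_matches_clt(self, rng):
        x = rng.standard_normal(1000)
        lo, hi = bootstrap_ci(x, n_boot=10_000, seed=1)
        expected = 2 * 1.96 / np.sqrt(1000)
        assert (hi - lo) == pytest.approx(expected, rel=0.2)

    def test_seed_reproducibility(self, rng):
        x = rng.standard_normal(50)
        assert bootstrap_ci(x, seed=9) == bootstrap_ci(x, seed=9)


class TestSpearman:
    def test_perfect_and_monotone(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        rho, p = spearman_corr(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_partial_on_shared_covariate_near_zero(self):
        rhos = []
        for s in range(50):
            rng = np.random.default_rng(s)
            c = rng.standard_normal(500)
            x = c + 0.5 * rng.standard_normal(500)
            y = rng.standard_normal(500)  # independent of x given anything
            rhos.append(spearman_corr(x, y, covariate=c)[0])
        assert abs(np.mean(rhos)) < 0.1

    def test_partial_removes_covariate_driven_association(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(500)
        x = c + 0.3 * rng.standard_normal(500)
        y = c + 0.3 * rng.standard_normal(500)
        raw = spearman_corr(x, y)[0]
        partial = spearman_corr(x, y, covariate=c)[0]
        assert raw > 0.7
        assert abs(partial) < 0.3


class TestSummaryTTest:
    @pytest.mark.parametrize(
        "summary, expected_t, expected_df",
        [
            ((70.21, 4.38, 116, 72.16, 5.29, 85), -2.86, 199),  # HC vs SCD age
            ((70.21, 4.38, 116, 73.45, 5.44, 142), -5.21, 256),  # HC vs MCI age
            ((71.73, 5.20, 22, 73.70, 3.40, 23), -1.51, 43),  # baseline age
            ((73.05, 4.85, 22, 75.87, 3.55, 23), -2.22, 43),  # follow-up age
            ((26.73, 3.06, 22, 23.41, 4.24, 23), 2.98, 43),  # follow-up MMSE
        ],
    )
    def test_reproduces_printed_statistics(self, summary, expected_t, expected_df):
        t, df, _ = ttest_from_summary(*summary)
        assert t == pytest.approx(expected_t, abs=0.05)
        assert df == expected_df

    def test_identical_summaries(self):
        t, df, ci = ttest_from_summary(5, 1, 20, 5, 1, 20)
        assert t == 0.0
        assert ci[0] < 0 < ci[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            ttest_from_summary(1, 1.0, 1, 2, 1.0, 10)


@given(
    p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
    q=st.floats(0.01, 0.4),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_property_matches_brute_force(p, q):
    _, mask = bh_fdr(p, q)
    np.testing.assert_array_equal(mask, brute_force_bh_mask(np.array(p), q))


class TestBattery:
    def test_row_accounting(self, small_cohort):
        table = run_stat_battery(small_cohort, metric="dfa", parcel_level=True)
        n_freqs = small_cohort.freqs.size
        n_parcels = small_cohort.maps[0].n_parcels
        wb = table[table["scope"] == "whole-brain"]
        assert (wb["contrast"] == "omnibus").sum() == n_freqs
        assert len(wb) == n_freqs + 3 * n_freqs
        assert (table["scope"] == "parcel").sum() == n_parcels * n_freqs * 3

    def test_adjusted_p_monotone_and_flags_consistent(self, small_cohort):
        table = run_stat_battery(small_cohort, metric="fei", parcel_level=False)
        finite = table["p_adj"].notna()
        assert (table.loc[finite, "p_adj"] >= table.loc[finite, "p"] - 1e-12).all()
        assert (table.loc[table["sig_0.01"], "p_adj"] <= 0.01 + 1e-12).all()

    def test_detects_planted_group_shift(self, small_cohort):
        table = run_stat_battery(small_cohort, metric="dfa", parcel_level=False)
        alpha_rows = table[
            (table["scope"] == "whole-brain")
            & (table["contrast"] == "omnibus")
            & (table["freq"] >= 7) & (table["freq"] < 12)
        ]
        assert alpha_rows["sig_0.05"].any()

    def test_percent_significant_summary(self, small_cohort):
        table = run_stat_battery(small_cohort, metric="dfa", parcel_level=True)
        pct = percent_significant(table, "HC-MCI", alpha=0.05)
        assert len(pct) == small_cohort.freqs.size
        assert (0 <= pct).all() and (pct <= 100).all()

    def test_null_family_discovery_rate_controlled(self):
        from neurocrit.synth import CohortSpec, generate_cohort

        hits = 0
        reps = 100
        for rep in range(reps):
            spec = CohortSpec(group_sizes=(12, 12, 12), n_parcels=3, n_freqs=4,
                              dfa_shift={}, fei_shift={}, seed=5000 + rep)
            cohort = generate_cohort(spec)
            table = run_stat_battery(cohort, metric="dfa", parcel_level=False,
                                     config=StatConfig(q_wholebrain=0.1))
            omnibus = table[table["contrast"] == "omnibus"]
            hits += (omnibus["p_adj"] <= 0.1).any()
        assert hits / reps <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / reps)
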