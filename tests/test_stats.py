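"""Normality gating, group comparisons, and intraclass correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import adrenadc as ad
from _oracles import icc_two_way, welch_from_summary


class TestNormality:
    def test_perfect_normal_quantile_sample_scores_near_one(self):
        n = 200
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        w, p = ad.test_normality(x)
        assert w > 0.995
        assert p > 0.9

    def test_exponential_samples_usually_rejected(self):
        """Power check against a clearly skewed alternative: the reference
        Shapiro-Wilk rejects n = 20 exponential draws about 84% of the
        time, so 200 seeded replicates comfortably clear 75%."""
        rng = np.random.default_rng(2024)
        rejected = sum(
            ad.test_normality(rng.exponential(size=20))[1] < 0.05 for _ in range(200)
        )
        assert rejected >= 150

    def test_constant_sample_rejected(self):
        with pytest.raises(ad.ValidationError):
            ad.test_normality([3.0, 3.0, 3.0, 3.0])

    def test_tiny_sample_rejected(self):
        with pytest.raises(ad.ValidationError):
            ad.test_normality([1.0, 2.0])


class TestCompareGroups:
    def test_normal_samples_take_t_branch_and_detect_shift(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.5, 0.2, 12)
        b = rng.normal(1.5 - 0.3, 0.2, 20)  # 1.5 SD effect
        res = ad.compare_groups(a, b)
        assert res.test_name == "t"
        assert res.p_value < 0.05

    def test_identical_groups_give_p_one_under_rank_branch(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = ad.compare_groups(np.repeat(x, 2), np.repeat(x, 2))
        # massive ties force the rank branch via the normality gate failure
        # or give p = 1 either way
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        lo, hi = res.ci_95_of_difference
        assert lo <= 0.0 <= hi

    def test_skewed_data_takes_rank_branch(self):
        rng = np.random.default_rng(11)
        a = rng.exponential(1.0, 25)
        b = rng.exponential(1.0, 25)
        res = ad.compare_groups(a, b)
        assert res.test_name == "mann_whitney"

    def test_constant_shift_lands_inside_difference_ci(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.4, 0.2, 15)
        b = a + 0.25
        res = ad.compare_groups(b, a)
        assert res.test_name == "t"
        lo, hi = res.ci_95_of_difference
        assert lo <= 0.25 <= hi

    def test_zero_variance_group_falls_back_to_rank_branch(self):
        res = ad.compare_groups([2.0] * 6, [1.0, 2.0, 3.0, 2.5, 1.5, 2.2])
        assert res.test_name == "mann_whitney"

    def test_raw_welch_agrees_with_own_summaries_to_1e10(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.44, 0.23, 12)
        b = rng.normal(1.23, 0.21, 20)
        raw = ad.compare_groups(a, b)
        assert raw.test_name == "t"
        summ = ad.compare_groups_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-10)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
        np.testing.assert_allclose(raw.ci_95_of_difference, summ.ci_95_of_difference, atol=1e-10)


class TestCompareFromSummary:
    @pytest.mark.parametrize("m1,s1,n1,m2,s2,n2", [
        (1.44, 0.23, 12, 1.23, 0.21, 20),  # right-gland group summaries
        (1.58, 0.22, 12, 1.32, 0.23, 20),  # left-gland group summaries
    ])
    def test_gland_summaries_significant_and_match_textbook_welch(self, m1, s1, n1, m2, s2, n2):
        res = ad.compare_groups_from_summary(m1, s1, n1, m2, s2, n2)
        t_ref, df_ref, p_ref = welch_from_summary(m1, s1, n1, m2, s2, n2)
        assert res.p_value < 0.05
        assert res.statistic == pytest.approx(t_ref, abs=1e-12)
        assert res.df == pytest.approx(df_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)
        assert res.ci_95_of_difference[0] > 0  # difference excludes zero

    def test_equal_summaries_give_t_zero_p_one(self):
        res = ad.compare_groups_from_summary(1.4, 0.2, 12, 1.4, 0.2, 12)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_from_stats(self):
        res = ad.compare_groups_from_summary(1.58, 0.22, 12, 1.32, 0.23, 20)
        ref = sps.ttest_ind_from_stats(1.58, 0.22, 12, 1.32, 0.23, 20, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("kw", [
        dict(mean1=1, sd1=0, n1=5, mean2=1, sd2=1, n2=5),
        dict(mean1=1, sd1=1, n1=1, mean2=1, sd2=1, n2=5),
    ])
    def test_invalid_summaries_rejected(self, kw):
        with pytest.raises(ad.ValidationError):
            ad.compare_groups_from_summary(**kw)


def random_table(rng, n=10, k=2, sd_subj=0.2, sd_noise=0.1):
    return 1.4 + rng.normal(0, sd_subj, (n, 1)) + rng.normal(0, sd_noise, (n, k))


class TestICC:
    def test_matches_loop_based_anova_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            tab = random_table(rng, n=int(rng.integers(5, 15)), k=int(rng.integers(2, 5)))
            ref = icc_two_way(tab.tolist())
            for variant in ad.ICC_VARIANTS:
                assert ad.compute_icc(tab, variant).icc == pytest.approx(
                    ref[variant], abs=1e-10
                )

    def test_matches_pingouin_two_way_forms(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        tab = random_table(rng, n=12, k=3)
        long = pd.DataFrame(
            [(i, j, tab[i, j]) for i in range(12) for j in range(3)],
            columns=["subject", "rater", "value"],
        )
        ref = pg.intraclass_corr(long, "subject", "rater", "value").set_index("Type")
        pairs = {
            "agreement_single": "ICC(A,1)", "agreement_average": "ICC(A,k)",
            "consistency_single": "ICC(C,1)", "consistency_average": "ICC(C,k)",
        }
        for variant, typ in pairs.items():
            mine = ad.compute_icc(tab, variant)
            assert mine.icc == pytest.approx(ref.loc[typ, "ICC"], abs=1e-12)
            # pingouin rounds its CI to two decimals
            np.testing.assert_allclose(mine.ci_95, list(ref.loc[typ, "CI95"]), atol=6e-3)

    def test_identical_raters_give_icc_one_for_every_variant(self):
        col = np.array([1.1, 1.3, 1.5, 1.2, 1.4, 1.6])
        tab = np.column_stack([col, col, col])
        for variant in ad.ICC_VARIANTS:
            res = ad.compute_icc(tab, variant)
            assert res.icc == pytest.approx(1.0, abs=1e-12)
            assert res.ci_95[0] <= res.icc <= res.ci_95[1]

    def test_systematic_rater_shift_perfect_consistency_imperfect_agreement(self):
        col = np.array([1.1, 1.3, 1.5, 1.2, 1.4, 1.6])
        tab = np.column_stack([col, col + 0.3])
        assert ad.compute_icc(tab, "consistency_single").icc == pytest.approx(1.0, abs=1e-12)
        assert ad.compute_icc(tab, "agreement_single").icc < 1.0

    def test_invariant_to_common_shift_and_positive_scaling(self):
        rng = np.random.default_rng(31)
        tab = random_table(rng)
        for variant in ad.ICC_VARIANTS:
            base = ad.compute_icc(tab, variant).icc
            assert ad.compute_icc(tab + 5.0, variant).icc == pytest.approx(base, abs=1e-9)
            assert ad.compute_icc(tab * 3.2, variant).icc == pytest.approx(base, abs=1e-9)

    def test_reader_tables_recover_analytic_variance_ratio(self):
        """Single-measure agreement ICC estimates
        sigma_subject^2 / (sigma_subject^2 + sigma_bias^2 + sigma_noise^2);
        with sigma = (0.2, 0.1, 0.1) the target ratio is 2/3."""
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(200):
            truths = 1.4 + rng.normal(0, 0.2, 20)
            biases = rng.normal(0, 0.1, 2)
            ms = ad.generate_reader_measurements(
                truths, biases, 0.1, n_readers=2, seed=int(rng.integers(2**31))
            )
            tab = np.array([
                [m.mean_adc for m in ms if m.reader_id == f"reader{r}"] for r in (1, 2)
            ]).T
            estimates.append(ad.compute_icc(tab, "agreement_single").icc)
        assert np.mean(estimates) == pytest.approx(2.0 / 3.0, abs=0.05)

    def test_zero_between_subject_variance_is_degenerate(self):
        tab = np.tile([1.0, 2.0], (6, 1))
        with pytest.raises(ad.DegenerateTableError):
            ad.compute_icc(tab)

    @pytest.mark.parametrize("bad", [
        np.ones((4, 2)),                      # too few subjects
        np.ones((6, 1)),                      # one rater
        np.array([[1.0, np.nan]] * 6),        # missing cell
    ])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises((ad.ValidationError, ad.DegenerateTableError)):
            ad.compute_icc(bad)
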