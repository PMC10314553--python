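"""Cohort statistics: worked examples, calibration and monotonicity."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import airwaymorph as am
from airwaymorph.stats import PowerSpec, paired_t_power


class TestStudentT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = am.student_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_weight_row_from_summaries(self):
        """Group weight summaries (n=17 each) reproduce the printed p≈0.69."""
        res = am.student_t((17, 70.76, 16.01), (17, 68.59, 15.89))
        assert res.p == pytest.approx(0.693, abs=0.005)
        assert res.df == 32

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        res = am.student_t(a, a + 10.0)
        assert res.p < 1e-6

    def test_welch_differs_under_unequal_variance(self):
        pooled = am.student_t((10, 0.0, 1.0), (40, 1.0, 10.0))
        welch = am.student_t((10, 0.0, 1.0), (40, 1.0, 10.0), welch=True)
        assert pooled.df != pytest.approx(welch.df)

    def test_constant_groups_error(self):
        with pytest.raises(am.StatisticsError):
            am.student_t(np.ones(5), np.ones(5))

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        assert am.student_t(a, b).p == pytest.approx(am.student_t(b, a).p)


class TestPairedT:
    def test_zero_variance_error_message(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(am.StatisticsError, match="zero difference variance"):
            am.paired_t(x, x.copy())

    def test_hand_computed(self):
        # differences (1,2,3): mean 2, sd 1, t = 2*sqrt(3), df 2
        res = am.paired_t(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_power_for_programmed_shift(self):
        """Effect mean 2000 / sd 1500 at n=17 is detected essentially always."""
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(500):
            d = rng.normal(2000, 1500, 17)
            rejections += am.paired_t(np.zeros(17), d).p < 0.05
        assert rejections / 500 > 0.99


class TestKSNormality:
    def test_calibration_under_null(self):
        """Monte-Carlo p is calibrated: ~95% of null samples keep p > 0.05.

        The +1-corrected p is slightly conservative (true pass rate ≈ 0.957),
        so with 1000 replicates a 0.94 bound sits ~2.5 binomial SDs below it."""
        rng = np.random.default_rng(0)
        over = sum(am.ks_normality(rng.standard_normal(100), reps=300,
                                   seed=k).p > 0.05
                   for k in range(1000))
        assert over / 1000 >= 0.94

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rejected = sum(am.ks_normality(rng.exponential(size=100), reps=1000,
                                       seed=k).p < 0.05
                       for k in range(100))
        assert rejected >= 90

    def test_too_small_sample(self):
        with pytest.raises(am.StatisticsError):
            am.ks_normality(np.array([1.0, 2.0, 3.0, 4.0]))

    def test_constant_sample(self):
        with pytest.raises(am.StatisticsError):
            am.ks_normality(np.ones(20))

    def test_against_statsmodels_lilliefors(self):
        """Independent oracle: the table-based Lilliefors statistic agrees and
        its p lands in the same region as the Monte-Carlo p."""
        from statsmodels.stats.diagnostic import lilliefors
        rng = np.random.default_rng(4)
        x = rng.normal(3, 2, 80)
        d_sm, p_sm = lilliefors(x, dist="norm")
        res = am.ks_normality(x, reps=5000, seed=0)
        assert res.statistic == pytest.approx(d_sm, abs=5e-3)
        assert (res.p > 0.05) == (p_sm > 0.05)


class TestAncova:
    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        group = np.repeat(["A", "B"], 100)
        p_age, p_group = [], []
        for _ in range(200):
            y = rng.normal(size=200)
            age = rng.normal(45, 10, 200)
            pa, pg = am.ancova_group_age(y, group, age)
            p_age.append(pa)
            p_group.append(pg)
        assert sps.kstest(p_age, "uniform").pvalue > 0.01
        assert sps.kstest(p_group, "uniform").pvalue > 0.01

    def test_age_signal_detected_group_not(self):
        rng = np.random.default_rng(1)
        group = np.repeat(["A", "B"], 100)
        age = rng.normal(45, 10, 200)
        y = 2 * age + rng.normal(0, 5, 200)
        p_age, p_group = am.ancova_group_age(y, group, age)
        assert p_age < 0.001 and p_group > 0.05

    def test_group_signal_detected_age_not(self):
        rng = np.random.default_rng(2)
        group = np.repeat(["A", "B"], 100)
        age = rng.normal(45, 10, 200)
        y = np.where(group == "A", 0.0, 3.0) + rng.normal(0, 1, 200)
        p_age, p_group = am.ancova_group_age(y, group, age)
        assert p_group < 1e-6 and p_age > 0.01

    def test_constant_age_error(self):
        with pytest.raises(am.StatisticsError):
            am.ancova_group_age([1.0, 2, 3, 4], ["A", "A", "B", "B"],
                                [40.0, 40, 40, 40])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert am.pearson_correlation(x, x).estimate == pytest.approx(1.0)

    def test_strong_negative(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        res = am.pearson_correlation(x, -x + rng.normal(0, 0.1, 50))
        assert res.estimate < -0.9

    def test_constant_input_error(self):
        with pytest.raises(am.StatisticsError):
            am.pearson_correlation(np.ones(5), np.arange(5.0))


class TestChiSquare:
    def test_sex_split_worked_example(self):
        res = am.chi_square_2x2([[9, 8], [7, 10]])
        assert res.statistic == pytest.approx(0.472, abs=5e-4)
        assert res.p == pytest.approx(0.492, abs=5e-4)

    def test_balanced_table(self):
        res = am.chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_perfect_association(self):
        assert am.chi_square_2x2([[20, 0], [0, 20]]).p < 1e-6

    def test_transpose_invariance(self):
        t = np.array([[9, 8], [7, 10]])
        assert am.chi_square_2x2(t).statistic == \
            pytest.approx(am.chi_square_2x2(t.T).statistic)

    def test_zero_margin_error(self):
        with pytest.raises(am.StatisticsError):
            am.chi_square_2x2([[0, 0], [5, 5]])


class TestSampleSize:
    def test_airway_volume_change_effect(self):
        """The planning effect (mean 1261.6, SD 1476.2) needs at least 16
        subjects at 90% power and two-sided alpha 0.05."""
        n = am.sample_size_paired_t(PowerSpec(1261.6, 1476.2, 0.05, 0.90))
        assert n >= 16
        assert paired_t_power(n, 1261.6 / 1476.2) >= 0.90
        assert paired_t_power(n - 1, 1261.6 / 1476.2) < 0.90

    def test_classic_half_sd_effect(self):
        assert am.sample_size_paired_t(PowerSpec(0.5, 1.0, 0.05, 0.80)) == 34

    def test_huge_effect_saturates(self):
        assert am.sample_size_paired_t(PowerSpec(10.0, 1.0, 0.05, 0.90)) <= 3

    @given(d1=st.floats(0.3, 2.0), d2=st.floats(0.3, 2.0))
    @settings(deadline=None, max_examples=20)
    def test_monotone_in_effect_size(self, d1, d2):
        lo, hi = sorted((d1, d2))
        n_hi = am.sample_size_paired_t(PowerSpec(hi, 1.0))
        n_lo = am.sample_size_paired_t(PowerSpec(lo, 1.0))
        assert n_hi <= n_lo

    def test_monotone_in_power_target(self):
        ns = [am.sample_size_paired_t(PowerSpec(0.6, 1.0, power=p))
              for p in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))


class TestTreatmentSuccess:
    @pytest.mark.parametrize("t0,t1,expected", [
        (40, 9, True),    # post-treatment AHI below 10
        (40, 20, True),   # exactly 50% reduction
        (30, 22, False),  # neither criterion
        (8, 9, True),     # still below 10
        (100, 51, False),
    ])
    def test_rule(self, t0, t1, expected):
        assert am.classify_treatment_success(t0, t1) is expected

    def test_negative_ahi_rejected(self):
        with pytest.raises(am.ValidationError):
            am.classify_treatment_success(-1, 5)
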