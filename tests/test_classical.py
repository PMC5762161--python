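"""Naive and subject-based analyses against hand computations and oracles."""

import numpy as np
import pytest
from scipy import stats

from uoastats.classical import (
    fit_logistic_glm,
    odds_ratio_2x2,
    pooled_t_test,
    subject_based_t_test,
    subject_summaries,
)
from uoastats.datasets import remove_fraction
from uoastats.errors import ValidationError

#: per-subject mean lymph node sizes, subjects 1-12, 2 d.p.
SUBJECT_MEANS = [1.85, 2.78, 1.79, 2.24, 3.15, 2.60, 2.42, 1.57, 1.82, 2.26, 2.02, 2.62]


class TestPooledTTest:
    def test_naive_analysis_of_size_data(self, lymph_size):
        """Pooling all 72 slices treats them as independent and finds a
        'significant' RT effect on 70 df."""
        df = lymph_size.frame
        res = pooled_t_test(df["value"].to_numpy(), df["group"].to_numpy())
        assert res.difference == pytest.approx(0.283, abs=1e-3)
        assert res.t == pytest.approx(2.501, abs=1e-3)
        assert res.df == 70
        assert res.ci == pytest.approx((0.057, 0.508), abs=1e-3)
        assert res.p == pytest.approx(0.015, abs=1e-3)

    def test_hand_computed_example(self):
        res = pooled_t_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.difference == pytest.approx(-3.0)
        assert res.pooled_var == pytest.approx(1.0)
        assert res.sed == pytest.approx(np.sqrt(2.0 / 3.0))
        assert abs(res.t) == pytest.approx(3.674, abs=1e-3)

    def test_identical_groups_give_t_zero(self):
        res = pooled_t_test([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_zero_variance_flagged(self):
        with pytest.raises(ValidationError, match="zero"):
            pooled_t_test([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])

    def test_agrees_with_scipy_on_random_data(self, rng):
        """Independent oracle: scipy.stats.ttest_ind over 1000 random datasets."""
        for _ in range(1000):
            n1, n2 = rng.integers(2, 20, size=2)
            x1, x2 = rng.normal(size=n1), rng.normal(1.0, 2.0, size=n2)
            res = pooled_t_test(
                np.concatenate([x1, x2]), ["a"] * n1 + ["b"] * n2
            )
            t_ref, p_ref = stats.ttest_ind(x1, x2, equal_var=True)
            assert res.t == pytest.approx(t_ref, rel=1e-10)
            assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_reference_flag_flips_sign(self, lymph_size):
        df = lymph_size.frame
        a = pooled_t_test(df["value"], df["group"], reference="None")
        b = pooled_t_test(df["value"], df["group"], reference="Short RT")
        assert a.difference == pytest.approx(-b.difference)


class TestSubjectBased:
    def test_summary_means_match_printed_values(self, lymph_size):
        summ = subject_summaries(lymph_size)
        assert len(summ) == 12
        # printed to 2 d.p.; subject 8 sits exactly on a rounding boundary
        # (1.575), so compare at half-unit-in-last-place tolerance
        np.testing.assert_allclose(summ["summary"], SUBJECT_MEANS, atol=5.01e-3)

    def test_single_record_subject_summary_is_identity(self):
        from uoastats.datasets import NestedDataset
        import pandas as pd

        ds = NestedDataset(
            pd.DataFrame(
                {
                    "group": ["a", "a", "b", "b"],
                    "subject": ["1", "2", "3", "4"],
                    "value": [1.0, 2.0, 3.0, 4.0],
                }
            )
        )
        summ = subject_summaries(ds)
        assert summ["summary"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_subject_t_test_on_size_data(self, lymph_size):
        res = subject_based_t_test(lymph_size)
        assert res.difference == pytest.approx(0.283, abs=1e-3)
        assert res.t == pytest.approx(1.043, abs=1e-3)
        assert res.df == 10
        assert res.ci == pytest.approx((-0.321, 0.886), abs=1e-3)
        assert res.p == pytest.approx(0.322, abs=1e-3)

    def test_group_means_match_naive_on_balanced_data(self, lymph_size):
        """Balanced averaging: identical group means, wider interval."""
        df = lymph_size.frame
        naive = pooled_t_test(df["value"], df["group"])
        subj = subject_based_t_test(lymph_size)
        assert subj.difference == pytest.approx(naive.difference, abs=1e-12)
        assert subj.sed > naive.sed  # positive within-subject correlation
        assert subj.ci[1] - subj.ci[0] > naive.ci[1] - naive.ci[0]

    def test_unbalanced_summaries_warn(self, lymph_size):
        unb = remove_fraction(lymph_size, 0.5, seed=3)
        with pytest.warns(UserWarning, match="unequal"):
            summ = subject_summaries(unb)
        assert len(summ) == 12

    def test_one_record_per_subject_collapses_to_pooled(self, rng):
        import pandas as pd
        from uoastats.datasets import NestedDataset

        vals = rng.normal(size=10)
        ds = NestedDataset(
            pd.DataFrame(
                {
                    "group": ["a"] * 5 + ["b"] * 5,
                    "subject": [str(i) for i in range(10)],
                    "value": vals,
                }
            )
        )
        subj = subject_based_t_test(ds)
        pooled = pooled_t_test(vals, ["a"] * 5 + ["b"] * 5)
        assert subj.t == pytest.approx(pooled.t, rel=1e-12)
        assert subj.df == pooled.df


class TestOddsRatio:
    def test_printed_2x2_example(self):
        res = odds_ratio_2x2(43, 82, 79, 46)
        assert res.odds_ratio == pytest.approx(0.31, abs=5e-3)
        assert res.se_log_or == pytest.approx(0.264, abs=1e-3)

    def test_symmetric_table_gives_unity(self):
        assert odds_ratio_2x2(7, 3, 7, 3).odds_ratio == pytest.approx(1.0)

    def test_unit_cells(self):
        res = odds_ratio_2x2(1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.se_log_or == pytest.approx(2.0)

    def test_zero_cell_needs_continuity(self):
        with pytest.raises(ValidationError, match="zero cell"):
            odds_ratio_2x2(0, 5, 3, 2)
        res = odds_ratio_2x2(0, 5, 3, 2, continuity=True)
        assert res.odds_ratio > 0


class TestLogisticGLM:
    def test_count_fixture_reproduces_naive_logistic(self, lymph_count):
        res = fit_logistic_glm(lymph_count)
        assert res.odds_ratio == pytest.approx(0.31, abs=5e-3)
        assert res.ci == pytest.approx((0.18, 0.51), abs=5e-3)
        assert res.se_log_or == pytest.approx(0.264, abs=1e-3)
        assert res.p < 0.001

    def test_matches_2x2_collapse_exactly(self, lymph_count):
        """With a single binary covariate the GLM is saturated on the
        collapsed table: log-OR and SE agree to >= 10 significant figures."""
        res = fit_logistic_glm(lymph_count)
        tab = odds_ratio_2x2(43, 82, 79, 46)
        # fixture reference is None, so the GLM coefficient is Short RT vs None
        assert res.log_or == pytest.approx(tab.log_or, rel=1e-10)
        assert res.se_log_or == pytest.approx(tab.se_log_or, rel=1e-10)

    def test_cross_check_against_statsmodels(self, lymph_count):
        sm = pytest.importorskip("statsmodels.api")
        df = lymph_count.frame
        y = np.c_[df["events"], df["trials"] - df["events"]]
        X = sm.add_constant((df["group"] == "Short RT").to_numpy(float))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        res = fit_logistic_glm(lymph_count)
        assert res.coef == pytest.approx(ref.params[1], rel=1e-8)
        assert res.se_coef == pytest.approx(ref.bse[1], rel=1e-6)

    def test_parameter_recovery_large_n(self, rng):
        import pandas as pd
        from uoastats.datasets import NestedDataset
        from scipy.special import expit

        beta0, beta1 = -0.5, 1.2
        n_per = 2000
        x = np.r_[np.zeros(n_per), np.ones(n_per)]
        k = rng.binomial(20, expit(beta0 + beta1 * x))
        ds = NestedDataset(
            pd.DataFrame(
                {
                    "group": np.where(x == 0, "a", "b"),
                    "subject": [str(i) for i in range(2 * n_per)],
                    "events": k,
                    "trials": 20,
                }
            ),
            outcome_kind="binomial",
        )
        res = fit_logistic_glm(ds)
        assert res.coef == pytest.approx(beta1, abs=4 * res.se_coef)
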