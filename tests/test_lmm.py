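"""REML nested LMM: printed-value reproduction, oracles, and properties."""

import numpy as np
import pytest

from uoastats.classical import subject_based_t_test
from uoastats.datasets import DesignLayout, remove_fraction
from uoastats.design import simulate_nested_dataset
from uoastats.errors import ValidationError
from uoastats.lmm import (
    VarianceComponents,
    anova_variance_components,
    diagnostics,
    fit_nested_lmm,
    icc,
    lrt_random_structure,
)


class TestSizeDataFit:
    def test_variance_components(self, size_fit):
        c = size_fit.components
        assert c.sigma_subject == pytest.approx(0.436, abs=1e-3)
        assert c.sigma_sample == pytest.approx(0.234, abs=1e-3)
        assert c.sigma_resid == pytest.approx(0.122, abs=1e-3)

    def test_component_intervals(self, size_fit):
        """Wald-on-log intervals reproduce the published ones within 15%."""
        published = {
            "sigma_subject": (0.262, 0.727),
            "sigma_sample": (0.151, 0.362),
            "sigma_resid": (0.100, 0.149),
        }
        for name, (lo, hi) in published.items():
            got_lo, got_hi = size_fit.component_ci[name]
            assert got_lo == pytest.approx(lo, rel=0.15)
            assert got_hi == pytest.approx(hi, rel=0.15)

    def test_fixed_effect_inference(self, size_fit):
        d = size_fit.group_difference
        assert d["difference"] == pytest.approx(0.283, abs=1e-3)
        assert d["df"] == 10
        assert d["t"] == pytest.approx(1.043, abs=1e-3)
        assert d["ci"] == pytest.approx((-0.321, 0.886), abs=1e-3)

    def test_variance_ratios(self, size_fit):
        """Between-subject variance ~3.5x the sample level, ~13x the slices."""
        c = size_fit.components
        assert c.sigma_subject**2 / c.sigma_sample**2 == pytest.approx(3.5, abs=0.2)
        assert c.sigma_subject**2 / c.sigma_resid**2 == pytest.approx(13.0, abs=0.5)

    def test_icc(self, size_fit):
        assert icc(size_fit.components) == pytest.approx(0.733, abs=0.01)

    def test_lrt_against_subject_only_model(self, size_fit, size_fit_subject_only):
        lrt, df, p, p_mix = lrt_random_structure(size_fit, size_fit_subject_only)
        assert lrt == pytest.approx(39.92, abs=0.05)
        assert df == 1
        assert p < 0.001 and p_mix < 0.001

    def test_residuals_are_observed_minus_fitted(self, size_fit, lymph_size):
        np.testing.assert_allclose(
            size_fit.residuals,
            lymph_size.frame["value"].to_numpy() - size_fit.fitted,
            atol=1e-12,
        )

    def test_cross_check_against_statsmodels_mixedlm(self, lymph_size):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = lymph_size.frame.copy()
        df["samp"] = df["subject"] + ":" + df["sample"]
        ref = smf.mixedlm(
            "value ~ group", df, groups="subject", re_formula="1",
            vc_formula={"samp": "0 + C(samp)"},
        ).fit(reml=True)
        fit = fit_nested_lmm(lymph_size)
        assert ref.cov_re.iloc[0, 0] == pytest.approx(
            fit.components.sigma_subject**2, rel=1e-3
        )
        assert ref.vcomp[0] == pytest.approx(fit.components.sigma_sample**2, rel=1e-3)
        assert ref.scale == pytest.approx(fit.components.sigma_resid**2, rel=1e-3)


class TestOracleAndProperties:
    def test_matches_anova_estimators_on_balanced_data(
        self, example1_layout, example1_components
    ):
        """On balanced data REML equals the closed-form expected-mean-squares
        estimators whenever those are interior (non-negative)."""
        for seed in range(5):
            data = simulate_nested_dataset(
                example1_layout, 0.4, example1_components, seed=seed
            )
            oracle = anova_variance_components(data)
            fit = fit_nested_lmm(data, compute_component_ci=False)
            if min(oracle.sigma_subject, oracle.sigma_sample) > 1e-6:
                assert fit.components.sigma_subject == pytest.approx(
                    oracle.sigma_subject, abs=1e-5
                )
                assert fit.components.sigma_sample == pytest.approx(
                    oracle.sigma_sample, abs=1e-5
                )
                assert fit.components.sigma_resid == pytest.approx(
                    oracle.sigma_resid, abs=1e-5
                )

    def test_reml_loglik_not_below_anova_start(self, simulated_balanced):
        """Optimizer sanity: the optimum dominates the method-of-moments
        start point."""
        from uoastats.lmm import _Blocks, _anova_start

        blocks = _Blocks(simulated_balanced, ("subject", "sample"))
        start_nll = blocks.profiled_negloglik(
            _anova_start(simulated_balanced, ("subject", "sample")), "REML"
        )
        fit = fit_nested_lmm(simulated_balanced, compute_component_ci=False)
        assert fit.loglik >= -start_nll - 1e-9

    def test_ml_loglik_exceeds_reml_criterion_shape(self, simulated_balanced):
        ml = fit_nested_lmm(simulated_balanced, method="ML", compute_component_ci=False)
        reml = fit_nested_lmm(simulated_balanced, method="REML", compute_component_ci=False)
        # different criteria; both finite, components close but not identical
        assert np.isfinite(ml.loglik) and np.isfinite(reml.loglik)
        assert ml.components.sigma_resid == pytest.approx(
            reml.components.sigma_resid, rel=0.2
        )

    def test_unbalanced_fit_stays_finite_and_differs_from_subject_t(self, lymph_size):
        unb = remove_fraction(lymph_size, 0.5, seed=1)
        fit = fit_nested_lmm(unb, compute_component_ci=False)
        c = fit.components
        assert c.sigma_subject > 0 and c.sigma_sample > 0 and c.sigma_resid > 0
        with pytest.warns(UserWarning, match="unequal"):
            tt = subject_based_t_test(unb)
        assert fit.group_difference["difference"] != pytest.approx(
            tt.difference, abs=1e-6
        )

    def test_identical_samples_hit_sample_variance_boundary(self, lymph_size):
        """When each subject's two samples carry identical values there is no
        sample-level variance at all, and the REML estimate must sit at the
        boundary (reported as ~0 with a flag, not an error)."""
        df = lymph_size.frame.copy()
        s1 = df[df["sample"] == "1"].set_index(["subject", "replicate"])["value"]
        mask = df["sample"] == "2"
        df.loc[mask, "value"] = s1.loc[
            list(zip(df.loc[mask, "subject"], df.loc[mask, "replicate"]))
        ].to_numpy()
        from uoastats.datasets import NestedDataset

        data = NestedDataset(df)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_nested_lmm(data, compute_component_ci=False)
        assert fit.boundary["sigma_sample"]
        assert fit.components.sigma_sample < 1e-3 * fit.components.sigma_resid
        assert not fit.boundary["sigma_subject"]

    def test_mismatched_fixed_effects_refused(self, size_fit, simulated_balanced):
        other = fit_nested_lmm(simulated_balanced, compute_component_ci=False)
        with pytest.raises(ValidationError):
            lrt_random_structure(size_fit, other)

    def test_identical_models_give_zero_lrt(self, size_fit):
        lrt, df, p, p_mix = lrt_random_structure(size_fit, size_fit)
        assert lrt == 0.0 and p == 1.0 and p_mix == 1.0

    def test_null_sample_variance_lrt_conservative(self, example1_layout):
        """Simulated under sigma_S = 0: the naive chi-square(1) LRT rejects at
        or below the nominal 5% level (boundary effect)."""
        comp = VarianceComponents(0.4, 0.0, 0.2)
        rejections = 0
        n_reps = 100
        import warnings

        for r in range(n_reps):
            data = simulate_nested_dataset(
                example1_layout, 0.0, comp, seed=np.random.default_rng([50, r])
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = fit_nested_lmm(data, ("subject", "sample"), compute_component_ci=False)
                red = fit_nested_lmm(data, ("subject",), compute_component_ci=False)
            _, _, p, _ = lrt_random_structure(full, red)
            rejections += p < 0.05
        # binomial(100, 0.05): observing > 10 would be a < 1% tail event
        assert rejections <= 10


class TestDiagnostics:
    def test_size_fit_diagnostics_shapes(self, size_fit):
        diag = diagnostics(size_fit)
        assert len(diag["per_subject"]) == 12
        assert diag["per_subject"]["n"].sum() == 72
        assert len(diag["qq"]) == 72

    def test_qq_of_normal_residuals_near_identity(self, rng):
        import pandas as pd
        from uoastats.datasets import NestedDataset

        # pure-noise two-level data: residuals should be close to Normal
        n_subj, m = 20, 30
        rows = []
        for s in range(n_subj):
            for j in range(m):
                rows.append(
                    ("a" if s < 10 else "b", f"s{s}", str(j), "1", rng.normal())
                )
        ds = NestedDataset(
            pd.DataFrame(rows, columns=["group", "subject", "sample", "replicate", "value"])
        )
        fit = fit_nested_lmm(ds, ("subject",), compute_component_ci=False)
        qq = diagnostics(fit)["qq"]
        slope = np.polyfit(qq["theoretical"], qq["observed"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_near_zero_residual_variance_limit(self, example1_layout):
        comp = VarianceComponents(0.5, 0.2, 1e-6)
        data = simulate_nested_dataset(example1_layout, 0.0, comp, seed=2)
        fit = fit_nested_lmm(data, compute_component_ci=False)
        assert np.max(np.abs(fit.residuals)) < 1e-4


class TestBalancedEquivalence:
    def test_fixture_equivalence_with_subject_t(self, size_fit, lymph_size):
        tt = subject_based_t_test(lymph_size)
        d = size_fit.group_difference
        assert d["difference"] == pytest.approx(tt.difference, abs=1e-8)
        assert d["se"] == pytest.approx(tt.sed, abs=1e-6)
        assert d["df"] == tt.df
        assert d["ci"] == pytest.approx(tt.ci, abs=1e-6)
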