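"""REML fit, boundary LRT, Satterthwaite ANOVA and heritability.

The frozen expected values in ``TestAgainstIndependentImplementation`` were
computed with the lme4/lmerTest R packages on the identical dataset
(regenerated deterministically from its seed), giving a fully independent
check of the variance components, restricted log-likelihood, fixed effects,
type-III F statistics, Satterthwaite denominator dfs and LRT statistics.
"""

import numpy as np
import pandas as pd
import pytest

from coldtol.lmm_reml import (
    ModelSpec,
    VarianceComponents,
    fit_reml,
    heritability,
    lrt_random_term,
    satterthwaite_anova,
)
from coldtol.synthetic_data import SimulationConfig, simulate_well_medians


@pytest.fixture(scope="module")
def paper_like_fit():
    table, _ = simulate_well_medians(SimulationConfig(seed=42))
    spec = ModelSpec()
    return table, spec, fit_reml(table, spec)


class TestRemlOracle:
    def test_balanced_oneway_equals_anova_closed_form(self, balanced_oneway):
        # groups A{1,2} B{3,4} C{5,6}: MSW = 0.5, MSB = 8,
        # var_group = (MSB - MSW)/2 = 3.75
        fit = fit_reml(balanced_oneway, ModelSpec(response="y", fixed=(), random=("group",)))
        assert fit.variances["group"] == pytest.approx(3.75, rel=1e-6)
        assert fit.var_residual == pytest.approx(0.5, rel=1e-6)

    def test_identical_responses_collapse_to_boundary(self):
        df = pd.DataFrame({"y": [5.0] * 12, "group": list("AABBCCDDEEFF")})
        fit = fit_reml(df, ModelSpec(response="y", fixed=(), random=("group",)))
        assert fit.variances["group"] == pytest.approx(0.0, abs=1e-12)
        assert fit.var_residual == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self, balanced_oneway):
        spec = ModelSpec(response="y", fixed=(), random=("group",))
        base = fit_reml(balanced_oneway, spec)
        scaled = balanced_oneway.assign(y=balanced_oneway["y"] * 10.0)
        fit10 = fit_reml(scaled, spec)
        assert fit10.variances["group"] == pytest.approx(100 * base.variances["group"], rel=1e-6)
        assert fit10.var_residual == pytest.approx(100 * base.var_residual, rel=1e-6)

    def test_shift_invariance(self, balanced_oneway):
        spec = ModelSpec(response="y", fixed=(), random=("group",))
        base = fit_reml(balanced_oneway, spec)
        shifted = balanced_oneway.assign(y=balanced_oneway["y"] + 1234.5)
        fit_s = fit_reml(shifted, spec)
        assert fit_s.variances["group"] == pytest.approx(base.variances["group"], rel=1e-8)
        assert fit_s.var_residual == pytest.approx(base.var_residual, rel=1e-8)
        assert fit_s.reml_loglik == pytest.approx(base.reml_loglik, abs=1e-8)


class TestAgainstIndependentImplementation:
    """Frozen lme4/lmerTest values for the seed-42 synthetic assay."""

    def test_variance_components_and_loglik(self, paper_like_fit):
        _, _, fit = paper_like_fit
        assert fit.variances["strain"] == pytest.approx(1549.779807, rel=1e-4)
        assert fit.variances["strain:treatment"] == pytest.approx(1075.433889, rel=1e-4)
        assert fit.var_residual == pytest.approx(1149.61854, rel=1e-5)
        assert fit.reml_loglik == pytest.approx(-2506.650407, abs=1e-4)

    def test_fixed_effects(self, paper_like_fit):
        _, _, fit = paper_like_fit
        beta = dict(zip(fit.beta_names, fit.beta))
        assert beta["(Intercept)"] == pytest.approx(756.0356183, rel=1e-6)
        assert beta["treatment[cold]"] == pytest.approx(-153.1911257, rel=1e-6)
        assert beta["design_id[D2]"] == pytest.approx(14.83895584, rel=1e-6)
        assert beta["design_id[D3]"] == pytest.approx(21.11440939, rel=1e-6)

    def test_type_iii_anova_with_satterthwaite(self, paper_like_fit):
        _, _, fit = paper_like_fit
        anova = {a.term: a for a in satterthwaite_anova(fit)}
        assert anova["treatment"].F == pytest.approx(74.17258128, rel=1e-4)
        assert anova["design_id"].F == pytest.approx(17.18051442, rel=1e-4)
        assert anova["treatment"].ndf == 1 and anova["design_id"].ndf == 2
        assert anova["treatment"].ddf == pytest.approx(6.0, rel=0.02)
        assert anova["design_id"].ddf == pytest.approx(488.0, rel=0.02)

    def test_lrt_statistics(self, paper_like_fit):
        table, spec, fit = paper_like_fit
        stats = {}
        for term in spec.random:
            reduced = fit_reml(table, spec.drop_random(term))
            stats[term] = lrt_random_term(fit, reduced)
        assert stats["strain"].statistic == pytest.approx(2.494714901, rel=1e-4)
        assert stats["strain:treatment"].statistic == pytest.approx(148.1175058, rel=1e-4)
        # boundary correction: halved chi-square(1) upper tail
        assert stats["strain"].p_halved == pytest.approx(0.1142 / 2, abs=2e-4)


class TestLrt:
    def test_zero_statistic_gives_half(self, balanced_oneway):
        from coldtol.lmm_reml import LrtResult
        from scipy.stats import chi2

        assert 0.5 * chi2.sf(0.0, 1) == pytest.approx(0.5)
        # through the API: identical models in likelihood -> clamped 0
        spec = ModelSpec(response="y", fixed=(), random=("group",))
        df = pd.DataFrame({"y": [1.0, 2, 1, 2, 1, 2], "group": list("AABBCC")})
        full = fit_reml(df, spec)
        reduced = fit_reml(df, spec.drop_random("group"))
        r = lrt_random_term(full, reduced)
        assert r.statistic >= 0.0
        assert 0 < r.p_halved <= 0.5

    def test_half_of_chi2_five_percent_point(self):
        from scipy.stats import chi2

        # halving the 0.05 upper-tail point of chi-square(1)
        assert 0.5 * chi2.sf(3.841458821, 1) == pytest.approx(0.025, abs=1e-6)

    def test_non_nested_models_rejected(self, balanced_oneway):
        spec = ModelSpec(response="y", fixed=(), random=("group",))
        fit = fit_reml(balanced_oneway, spec)
        with pytest.raises(ValueError, match="exactly one random term"):
            lrt_random_term(fit, fit)


class TestSatterthwaite:
    def test_fixed_only_collapses_to_residual_df(self, rng):
        # no random terms, balanced 2-level factor, n=20, p=2 -> ddf = 18
        df = pd.DataFrame(
            {
                "y": rng.normal(100, 5, size=20),
                "treatment": ["control"] * 10 + ["cold"] * 10,
            }
        )
        fit = fit_reml(df, ModelSpec(response="y", fixed=("treatment",), random=()))
        (res,) = satterthwaite_anova(fit)
        assert res.ddf == pytest.approx(18.0, abs=1e-4)

    def test_treatment_ddf_matches_interaction_stratum(self):
        # strains crossed with treatment and a strain:treatment random term:
        # for an interior fit the treatment error stratum is the interaction,
        # with (n_strains - 1)(n_treatments - 1) = 6 degrees of freedom
        table, _ = simulate_well_medians(SimulationConfig(seed=5, sd_strain_um=80.0))
        fit = fit_reml(table, ModelSpec())
        assert fit.variances["strain"] > 0  # interior optimum
        anova = {a.term: a for a in satterthwaite_anova(fit)}
        assert anova["treatment"].ddf == pytest.approx(6.0, abs=0.25)


class TestHeritability:
    @pytest.mark.parametrize(
        "vs,vg,ve,h2s,h2g",
        [(1.0, 1.0, 2.0, 0.25, 0.25), (0.0, 3.0, 1.0, 0.0, 0.75)],
    )
    def test_ratio_arithmetic(self, vs, vg, ve, h2s, h2g):
        h2 = heritability(VarianceComponents(vs, vg, ve))
        assert h2.h2_strain == pytest.approx(h2s)
        assert h2.h2_strain_treatment == pytest.approx(h2g)
        assert h2.h2_strain + h2.h2_strain_treatment <= 1.0

    def test_all_zero_components_undefined(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 0.0, 0.0))

    def test_sum_bounded_by_one_on_fits(self, paper_like_fit):
        _, _, fit = paper_like_fit
        h2 = heritability(fit.variance_components)
        assert 0 <= h2.h2_strain <= 1
        assert 0 <= h2.h2_strain_treatment <= 1
        assert h2.h2_strain + h2.h2_strain_treatment <= 1


def test_singular_fixed_design_raises():
    df = pd.DataFrame(
        {
            "y": [1.0, 2, 3, 4],
            "treatment": ["control", "control", "cold", "cold"],
            "dup": ["a", "a", "b", "b"],  # aliased with treatment
            "strain": ["S1", "S2", "S1", "S2"],
        }
    )
    with pytest.raises(np.linalg.LinAlgError):
        fit_reml(df, ModelSpec(response="y", fixed=("treatment", "dup"), random=("strain",)))


def test_nonfinite_response_rejected():
    df = pd.DataFrame({"y": [1.0, np.nan, 3.0], "group": list("ABC")})
    with pytest.raises(ValueError, match="non-finite"):
        fit_reml(df, ModelSpec(response="y", fixed=(), random=("group",)))
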