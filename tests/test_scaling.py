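"""Random-intercept scaling model: estimation, reduction, Wald test."""

import math
from dataclasses import replace

import numpy as np
import pytest

from spermscaling import (
    Dataset,
    GeneratorConfig,
    ModelSpec,
    fit_scaling_model,
    generate_metabolic_dataset,
    model_reduction,
    per_capita_exponent,
    wald_test,
)
from spermscaling.scaling import FitResult


def _pooled_ols(dataset, covariate=None):
    recs = dataset.fit_records()
    ln_c = np.log([r.concentration for r in recs])
    ln_r = np.log([r.rate for r in recs])
    cols = [np.ones(len(recs)), ln_c]
    if covariate:
        cols.append(np.array([1.0 if getattr(r, covariate) == "endotherm" else 0.0
                              for r in recs]))
    X = np.column_stack(cols)
    return np.linalg.lstsq(X, ln_r, rcond=None)[0]


class TestFit:
    def test_degenerate_noise_free_recovery(self):
        """With both variance components at zero the exponent is recovered
        exactly."""
        cfg = GeneratorConfig(seed=3, species_sd=0.0, residual_sd=0.0)
        synth = generate_metabolic_dataset(cfg)
        fit = fit_scaling_model(synth.dataset, ModelSpec())
        assert fit.beta == pytest.approx(0.87, abs=1e-6)
        assert math.exp(fit.covariate_effect) == pytest.approx(2.0, rel=1e-6)

    def test_single_species_equals_ols(self):
        """With one species the random intercept is absorbed by the fixed
        intercept and the fit collapses to ordinary least squares."""
        cfg = GeneratorConfig(seed=9, n_species=1, n_endotherm=0, obs_total=30)
        synth = generate_metabolic_dataset(cfg)
        fit = fit_scaling_model(synth.dataset, ModelSpec(covariate=None))
        ols = _pooled_ols(synth.dataset)
        assert fit.at_boundary
        assert fit.beta == pytest.approx(ols[1], abs=1e-8)
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_boundary_variance_matches_pooled_ols(self):
        """When the species variance is estimated at its 0 boundary, fixed
        effects equal pooled OLS."""
        synth = generate_metabolic_dataset(GeneratorConfig(seed=1, species_sd=0.0))
        fit = fit_scaling_model(synth.dataset, ModelSpec())
        assert fit.at_boundary
        assert fit.species_variance == 0.0
        ols = _pooled_ols(synth.dataset, covariate="thermoregulation")
        assert fit.beta == pytest.approx(ols[1], abs=1e-6)
        assert fit.covariate_effect == pytest.approx(ols[2], abs=1e-6)

    def test_default_simulation_recovery(self, default_fit):
        assert default_fit.beta == pytest.approx(0.87, abs=0.05)
        assert math.exp(default_fit.covariate_effect) == pytest.approx(2.0, abs=0.3)
        assert default_fit.converged
        assert default_fit.species_variance > 0
        assert default_fit.n_obs == 198 and default_fit.n_species == 49

    def test_concentration_unit_invariance(self, default_synth):
        """Rescaling every concentration by a constant moves only the
        intercept; the exponent is untouched."""
        scaled = Dataset(records=[replace(r, concentration=r.concentration * 1e3)
                                  for r in default_synth.records])
        base = fit_scaling_model(default_synth.dataset, ModelSpec())
        shifted = fit_scaling_model(scaled, ModelSpec())
        assert shifted.beta == pytest.approx(base.beta, abs=1e-8)
        assert shifted.intercept == pytest.approx(
            base.intercept - base.beta * math.log(1e3), abs=1e-6
        )

    def test_per_capita_response_shifts_exponent_by_one(self, default_synth, default_fit):
        pc_fit = fit_scaling_model(default_synth.dataset,
                                   ModelSpec(response="per_capita_rate"))
        assert pc_fit.beta == pytest.approx(default_fit.beta - 1.0, abs=1e-10)
        assert pc_fit.beta_se == pytest.approx(default_fit.beta_se, rel=1e-9)

    def test_matches_statsmodels_mixedlm(self, default_synth):
        """Independent cross-check of the profile-likelihood fitter."""
        smf = pytest.importorskip("statsmodels.formula.api")
        df = default_synth.dataset.to_frame()
        df["lnR"] = np.log(df["rate_ul_o2_per_h"])
        df["lnC"] = np.log(df["concentration_sperm_per_ml"])
        df["endo"] = (df["thermoregulation"] == "endotherm").astype(float)
        for reml, est in [(True, "REML"), (False, "ML")]:
            ref = smf.mixedlm("lnR ~ lnC + endo", df, groups=df["species"]).fit(reml=reml)
            fit = fit_scaling_model(default_synth.dataset, ModelSpec(estimation=est))
            assert fit.beta == pytest.approx(ref.params["lnC"], abs=1e-6)
            assert fit.covariate_effect == pytest.approx(ref.params["endo"], abs=1e-6)
            assert fit.species_variance == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
            assert fit.residual_variance == pytest.approx(float(ref.scale), abs=1e-5)
            assert fit.loglik == pytest.approx(float(ref.llf), abs=1e-6)

    def test_constant_covariate_is_singular(self):
        synth = generate_metabolic_dataset(GeneratorConfig(seed=2, n_endotherm=0,
                                                           n_species=10, obs_total=40))
        with pytest.raises(ValueError, match="singular|constant"):
            fit_scaling_model(synth.dataset, ModelSpec(covariate="thermoregulation"))

    def test_aic_identity(self, default_fit):
        k = default_fit.n_fixed + 2
        assert default_fit.aic == pytest.approx(2 * k - 2 * default_fit.loglik, abs=1e-9)


class TestModelReduction:
    def test_null_interaction_usually_dropped(self):
        """Generative interaction of zero: the LRT drops the interaction in
        at least 90% of seeded replicates at alpha 0.05."""
        dropped = 0
        seeds = range(100, 150)
        for seed in seeds:
            synth = generate_metabolic_dataset(GeneratorConfig(seed=seed))
            res = model_reduction(synth.dataset, ModelSpec(include_interaction=True))
            dropped += not res.reduction.interaction_retained
        assert dropped >= 0.9 * len(list(seeds))

    def test_real_interaction_usually_retained(self):
        retained = 0
        for seed in range(200, 215):
            synth = generate_metabolic_dataset(
                GeneratorConfig(seed=seed, interaction_effect=0.3)
            )
            res = model_reduction(synth.dataset, ModelSpec(include_interaction=True))
            retained += res.reduction.interaction_retained
        assert retained > 7  # majority of 15 seeds

    def test_alpha_one_returns_full_model(self, default_synth):
        res = model_reduction(default_synth.dataset,
                              ModelSpec(include_interaction=True), alpha=1.0)
        assert res.reduction.interaction_retained
        assert res.interaction_effect is not None

    def test_reduced_loglik_never_exceeds_full_under_ml(self):
        for seed in range(300, 310):
            synth = generate_metabolic_dataset(
                GeneratorConfig(seed=seed, n_species=12, n_endotherm=5, obs_total=60)
            )
            full = fit_scaling_model(synth.dataset,
                                     ModelSpec(include_interaction=True, estimation="ML"))
            red = fit_scaling_model(synth.dataset, ModelSpec(estimation="ML"))
            assert red.loglik <= full.loglik + 1e-8

    def test_requires_interaction_spec(self, default_synth):
        with pytest.raises(ValueError):
            model_reduction(default_synth.dataset, ModelSpec(include_interaction=False))


def _fit_stub(beta, se, n_obs, n_fixed):
    return FitResult(
        beta=beta, beta_se=se, intercept=0.0, intercept_se=1.0,
        covariate_effect=None, covariate_se=None,
        interaction_effect=None, interaction_se=None,
        species_variance=1.0, residual_variance=1.0, loglik=0.0, aic=0.0,
        n_obs=n_obs, n_species=10, n_fixed=n_fixed, converged=True,
        at_boundary=False, estimation="REML", spec=ModelSpec(covariate=None),
    )


class TestWald:
    def test_worked_example_against_linearity(self):
        """beta 0.87 with SE 0.04 on 198 residual df: |t| = 3.25, p near
        0.001."""
        fit = _fit_stub(0.87, 0.04, n_obs=201, n_fixed=3)
        res = wald_test(fit, null_value=1.0)
        assert res.df == 198
        assert abs(res.t_statistic) == pytest.approx(3.25, abs=0.005)
        assert res.p_value == pytest.approx(0.00136, abs=2e-4)

    def test_null_beta_gives_t_zero_p_one(self):
        res = wald_test(_fit_stub(1.0, 0.05, 100, 2), null_value=1.0)
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_t_distribution_tail(self):
        res = wald_test(_fit_stub(0.90, 0.05, 102, 2), null_value=1.0)
        assert res.t_statistic == pytest.approx(-2.0)
        assert res.df == 100
        assert res.p_value == pytest.approx(0.0482, abs=1e-3)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(_fit_stub(0.9, 0.0, 100, 2))


class TestPerCapitaExponent:
    @pytest.mark.parametrize("beta, expected", [(0.87, -0.13), (1.0, 0.0), (0.5, -0.5)])
    def test_shift_by_one(self, beta, expected):
        res = per_capita_exponent(_fit_stub(beta, 0.04, 100, 2))
        assert res.value == pytest.approx(expected)
        assert res.se == 0.04

    def test_rejects_per_capita_fit(self, default_synth):
        fit = fit_scaling_model(default_synth.dataset,
                                ModelSpec(response="per_capita_rate"))
        with pytest.raises(ValueError):
            per_capita_exponent(fit)
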