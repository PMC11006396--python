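"""Simulate a comparative dataset and estimate the density-metabolism
scaling exponent.

Generates 198 observations over 49 species from the default power-law
model (beta = 0.87, 2-fold endotherm offset), fits the random-intercept
mixed model and tests the exponent against 1 (= no density dependence of
per-capita metabolism).
"""

import math

from spermscaling import (
    GeneratorConfig,
    ModelSpec,
    fit_scaling_model,
    generate_metabolic_dataset,
    per_capita_exponent,
    percent_change_per_decade,
    round_half_up,
    wald_test,
)

synth = generate_metabolic_dataset(GeneratorConfig(seed=1))
fit = fit_scaling_model(synth.dataset, ModelSpec(covariate="thermoregulation"))
wald = wald_test(fit, null_value=1.0)
pc = per_capita_exponent(fit)
pct = percent_change_per_decade(pc.value)

print(f"records: {fit.n_obs} over {fit.n_species} species")
print(f"ejaculate-level exponent beta = {fit.beta:.3f} +/- {fit.beta_se:.3f}")
print(f"per-capita exponent beta - 1  = {pc.value:.3f} +/- {pc.se:.3f}")
print(f"Wald test vs beta = 1: t_{wald.df} = {wald.t_statistic:.2f}, p = {wald.p_value:.2g}")
print(f"endotherm offset: {math.exp(fit.covariate_effect):.2f}-fold "
      f"(generated: {synth.truth['endotherm_multiplier']}-fold)")
print(f"a 10-fold dilution raises per-capita rate by {pct:.1f}% (~{round_half_up(pct)}%)")
print()
print("beta < 1 with a small Wald p means sperm metabolic rate rises "
      "sub-linearly with concentration: per-capita metabolism is density dependent.")
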