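# spermscaling

Tools for estimating how sperm metabolic rate scales with sperm
concentration, and for auditing the bias introduced when metabolic rates
are "standardized" to a reference concentration by linear rescaling.

## The problem

Sperm respirometry is reported in incompatible ways: some studies report
the oxygen consumption actually measured (µl O₂ h⁻¹ at a stated sperm
concentration), while most rescale the rate linearly to a reference
concentration such as 10⁸ sperm ml⁻¹ (Z<sub>O₂</sub>). Linear rescaling
assumes ejaculate-level metabolic rate R is proportional to concentration
C. Comparative data say otherwise: R follows a power law

    R = a C^β,   β < 1,

so per-capita metabolic rate (∝ C^(β−1)) *rises* as an ejaculate is
diluted — the respiratory dilution effect. This package implements the
full analysis chain for quantifying that effect:

- **records** — a validated CSV data model for metabolic observations
  (species, thermoregulation, diluent, fertilization mode, handling,
  concentration, rate, reporting provenance), with exact back-calculation
  of measured rates from linearly standardized reports:
  R = Z / C_std × C_actual.
- **respirometry** — closed-chamber % air-saturation traces → V̇O₂:
  saturation window filter (default 100–75% AS), exhaustive local-slope
  search minimizing SE(slope)/|slope|, control correction, and unit
  conversion via the medium's oxygen capacitance (default 5.11 ml O₂ l⁻¹,
  seawater at 21°C) and chamber volume (default 750 µl).
- **scaling** — the core model: a Gaussian random-intercept mixed model of
  ln R on ln C with species as the random effect and an optional binary
  covariate (thermoregulation, diluent, or fertilization mode), fit by
  profiling the variance ratio with closed-form GLS; likelihood-ratio
  reduction of the covariate×concentration interaction (ML), REML for the
  reported model, and a Wald t-test of β against 1 (linearity = no density
  dependence).
- **effects** — log response ratios LRR = ln(X_L/X_H) between low- and
  high-concentration groups, and the per-decade headline
  100 × (10^−(β−1) − 1).
- **misestimation** — the bias of a linearly standardized report relative
  to the power-law truth at the reference concentration:
  linear/true = (C_actual/C_std)^(β−1), exposed per record and as a
  dataset audit.
- **synthetic** — a seeded generator for datasets with the assumed
  statistical structure (power-law mean, lognormal species and residual
  heterogeneity) and for respirometry traces, so every stage is testable
  against known truth.

## Worked example

```python
from spermscaling import (GeneratorConfig, ModelSpec, fit_scaling_model,
                          generate_metabolic_dataset, per_capita_exponent,
                          percent_change_per_decade, wald_test)

synth = generate_metabolic_dataset(GeneratorConfig(seed=1))
fit = fit_scaling_model(synth.dataset, ModelSpec(covariate="thermoregulation"))
print(fit.beta, fit.beta_se)          # 0.884 0.015
print(wald_test(fit, 1.0).p_value)    # 1.1e-12
print(per_capita_exponent(fit).value) # -0.116
print(percent_change_per_decade(per_capita_exponent(fit).value))  # 30.5
```

Running `python examples/01_simulate_and_fit.py` prints:

```
records: 198 over 49 species
ejaculate-level exponent beta = 0.884 +/- 0.015
per-capita exponent beta - 1  = -0.116 +/- 0.015
Wald test vs beta = 1: t_195 = -7.62, p = 1.1e-12
endotherm offset: 2.07-fold (generated: 2.0-fold)
a 10-fold dilution raises per-capita rate by 30.5% (~30%)
```

The fitted exponent (0.884 ± 0.015 for this seed) recovers the generative
β = 0.87 within sampling error; the Wald test rejects linearity, and the
per-decade line translates the per-capita exponent into the percentage
rise in per-cell metabolism caused by a 10-fold dilution. The other
scripts in `examples/` cover respirometry traces, the misestimation
audit, effect sizes and the end-to-end pipeline.

A thin CLI wraps the same functions
(`spermscaling simulate|harmonize|respo|fit|audit|run`); see
`spermscaling --help`.

## CSV schema

`species, thermoregulation {endotherm|ectotherm}, fertilization_mode
{internal|external}, diluent {carbohydrate_free|carbohydrate_containing},
diluent_job {activator|extender|unknown}, handling
{fresh|cooled|frozen_thawed|unknown}, concentration_sperm_per_ml,
rate_ul_o2_per_h, reporting {actual|standardized},
std_concentration_sperm_per_ml, assay_volume_ml, n_replicates, source`.

Standardized records must carry `std_concentration_sperm_per_ml`; a
standardized record without a measured concentration is retained but
flagged and excluded from fits. Malformed rows fail validation with their
line numbers — nothing is silently dropped.

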