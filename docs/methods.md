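# Methods

## Model

Ejaculate-level sperm metabolic rate R (µl O₂ h⁻¹) at sperm concentration
C (sperm ml⁻¹) is modelled as a power law with lognormal heterogeneity,
analysed on the natural-log scale:

    ln R_ij = α + β ln C_ij + γ x_i (+ η x_i ln C_ij) + u_i + ε_ij
    u_i ~ N(0, τ²),   ε_ij ~ N(0, σ²)

with i indexing species and x a binary species- or record-level covariate
(thermoregulation endo/ecto, diluent carbohydrate content, or
fertilization mode; reference levels ectotherm / carbohydrate-free /
external). β is the ejaculate-level density–metabolism exponent; dividing
by the number of sperm in the chamber (C × volume) shifts the log-log
slope by exactly −1, so the per-capita exponent is β − 1. β = 1 is the
"linear world" in which per-capita metabolism is density independent;
β < 1 means sperm respire less per cell in denser suspensions.

Headline translations: a 10-fold dilution multiplies per-capita rate by
10^−(β−1), i.e. a change of 100 × (10^−(β−1) − 1) percent (34.9% at
β = 0.87, presented as 35% under half-up integer rounding). The log
response ratio between a study's low- and high-concentration groups is
LRR = ln(X_L/X_H), left unweighted because weighting by study error would
suppress exactly the dose–response signal of interest; the group-level
test is a one-sample t on study-level LRRs.

## Estimation

The random-intercept structure makes V = σ²(I + θ Z Zᵀ) block diagonal
with θ = τ²/σ², and each species block inverse is I − θ/(1+θn_i) J. All
GLS quantities therefore reduce to per-species sums, and the profile
log-likelihood (ML or REML) is a smooth one-dimensional function of θ. We
evaluate it on a fixed 121-point grid in log θ ∈ [−10, 8], refine with
bounded scalar minimization (xatol 10⁻¹⁰), and compare against the exact
boundary θ = 0; a boundary optimum is reported via `at_boundary` and the
species variance set to 0, where fixed effects coincide with pooled OLS.
The fit is deterministic, requires no general-purpose mixed-model
dependency, and agrees with statsmodels' `MixedLM` to ~10⁻⁶ in
coefficients and ~10⁻⁶ in log-likelihood on the test datasets (that
agreement is asserted in the test suite; statsmodels is the cross-check,
never the implementation).

Conventions:

- ML is used wherever models are compared (likelihood-ratio χ² with 1 df
  for the interaction, ΔAIC); the selected model is refit under REML for
  reporting. AIC counts fixed effects plus both variance components.
- The Wald test of β against 1 uses t = (β̂ − 1)/SE(β̂) with residual
  degrees of freedom n_obs − n_fixed. This df convention is a
  documented choice; with ~200 observations the difference from
  alternatives is negligible.
- The per-capita response with constant chamber volume is fit via the
  exact reparameterization of the ejaculate-level model (subtracting
  ln C and ln V from the response shifts β by exactly 1 and leaves the
  likelihood unchanged); this avoids re-optimizing θ on an identical
  profile and makes the β_pc = β_ej − 1 identity hold to machine
  precision. Varying volumes fall back to a direct fit.
- Random slopes and phylogenetic covariance are out of scope; species
  enter only through intercepts. An extension would replace the diagonal
  random-effect covariance with a phylogenetic correlation matrix in the
  same profiled-GLS framework.

## Harmonization and misestimation

A standardized rate Z reported at reference concentration C_std but
measured at C_actual is back-calculated as R = Z/C_std × C_actual — the
exact inverse of the linear transformation the original report applied.
Standardized records whose measured concentration was never disclosed
cannot be inverted; they are retained with an `excluded_from_fit` flag
rather than deleted, so exclusions stay auditable.

The misestimation audit quantifies what linear standardization does under
the power law. Two algebraically equivalent routes are implemented
independently and cross-checked in tests to 10⁻¹²: the closed form
linear/true = (C_actual/C_std)^(β−1), and the explicit route (solve
a = R/C^β from the observation, predict the true rate a C_std^β, compare
with the linear extrapolation). The sign convention: positive percent
means the linear report overstates the true rate at the reference
concentration, which happens when the measurement was made below the
reference (ratio < 1, β < 1). The audit defaults to β = 0.87, the
among-species comparative estimate, and never refits β internally.

## Respirometry processing

Traces are % air saturation sampled about once per minute for 30–60 min
in sealed chambers. Processing: (1) restrict to the 100–75% AS window
(leading points above the upper bound are skipped, the series ends at the
first excursion; a chamber that never enters the window is excluded —
this is what happens to high-concentration chambers that deplete oxygen
before logging starts); (2) choose the slope by exhaustive search over
all contiguous windows of at least max(5, ⌈n/3⌉) points, minimizing the
relative slope error SE/|slope|, with ties broken toward longer windows
then earlier starts (relative errors below 10⁻¹² are treated as exact
ties so noise-free traces select the full window); (3) subtract the
arithmetic mean of control-chamber slopes; (4) convert:
V̇O₂ = |slope|/100 × capacitance × volume, with capacitance in
ml O₂ l⁻¹ (numerically µl O₂ ml⁻¹) and volume in ml. Positive net slopes
clamp to zero V̇O₂ with a warning rather than reporting negative
respiration. The window-selection objective and the control aggregation
rule are this package's documented choices; local-regression practice in
the field varies and no single objective is canonical.

Defaults — capacitance 5.11 ml O₂ l⁻¹ (air-saturated seawater at 21°C)
and 750 µl chambers — are run parameters, and the CLI makes them
mandatory-explicit to prevent silent unit errors.

## Synthetic data

The generator draws from the same model the fitter assumes, which is the
point: it provides ground truth for parameter-recovery and invariance
tests, not a simulacrum of real measurement error. Defaults mirror the
comparative compilation this pipeline targets: 198 observations across 49
species (21 endotherms), β = 0.87, a 2-fold endotherm offset
(γ = ln 2), species SD 1.0 and residual SD 0.5 on the ln scale, and
concentrations drawn log-uniformly over 10⁵–10⁹ sperm ml⁻¹ (the ~6-order
span of compiled data, with no density information available to justify
anything finer). The grand intercept defaults to −16.026, chosen once so
an ectotherm sample at 10⁸ sperm ml⁻¹ respires ≈1 µl O₂ h⁻¹ — a plausible
magnitude; the fit is invariant to it. Observations are allocated
⌊198/49⌋ = 4 per species with the remainder going one-each to the first
species in seeded-permutation order; the real compilation's per-species
counts are unknown, so this rule is a reproducible stand-in, not an
inference. Diluent is assigned carbohydrate-containing with probability
0.25 (roughly the compiled share) with a null effect by default;
endotherms are marked internal fertilizers and ectotherms external, the
dominant pairing. All randomness uses `numpy.random.default_rng` (PCG64);
dataset generation is bit-reproducible from (config, seed).

What the generator does *not* emulate: phylogenetic covariance among
species intercepts, heteroscedastic measurement error across methods and
decades, correlated within-study observations, digitization error, or
selective reporting. Passing recovery tests therefore shows the
estimator is correct under the assumed model, not that the model captures
every feature of literature data.

## Simulation scale

Parameter-recovery checks use 20 replicate datasets at the default size
(198 observations, 49 species) — enough for the Monte Carlo error of the
mean exponent (≈0.003) to sit well inside the ±0.02 recovery band.
Behavioral checks of the interaction LRT use 50 null replicates (type-I
behavior) and 15 with a ln-scale interaction of 0.3 (power); the
likelihood-nesting invariant is checked over 100 smaller replicates
(50 obs, 10 species). Each fit takes milliseconds, so the full suite runs
in seconds.

## Known limitations

- One grouping level only; multi-study-within-species structure is
  collapsed into the species intercept.
- The Wald df convention is residual df, not a Satterthwaite-style
  approximation; for small species counts the covariate-effect SE is the
  usual GLS plug-in and can be mildly anticonservative.
- The misestimation audit conditions on a supplied β; uncertainty in β
  is not propagated into the audit percentages.
- `saturation_filter` assumes monotone-ish decline; oscillating traces
  ending and re-entering the window contribute only their first in-window
  run.
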