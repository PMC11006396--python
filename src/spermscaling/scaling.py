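"""Log-log density-metabolism scaling model with species random intercepts.

The model for ejaculate-level metabolic rate R at sperm concentration C is

    ln R_ij = α + β ln C_ij + γ x_i (+ η x_i ln C_ij) + u_i + ε_ij,
    u_i ~ N(0, τ²),   ε_ij ~ N(0, σ²),

where i indexes species, x is an optional binary covariate
(thermoregulation, diluent or fertilization mode) and β is the scaling
exponent: β = 1 means per-capita metabolism is density independent, while
β < 1 means sperm in denser suspensions respire less per cell. The
per-capita exponent is β − 1 by the algebra of dividing the rate by
concentration × volume.

Estimation profiles the variance ratio θ = τ²/σ² on a one-dimensional
bounded search with closed-form GLS fixed effects at each candidate;
because the random-effect design is a block one-way layout, every matrix
operation reduces to per-species sums, making the fit deterministic and
fast. Maximum likelihood (ML) is used for likelihood-ratio and AIC
comparisons, REML for reported final models.

Model reduction mirrors the multistep approach used in comparative
analyses: fit the full model with the covariate×concentration interaction
under ML, drop the interaction when its likelihood-ratio test is
non-significant, and refit the selected model under the requested
estimation mode. A Wald t-test against β = 1 asks whether metabolism is
density dependent at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .records import Dataset, per_capita_rate

#: Reference level per covariate; the fitted offset is the effect of the
#: other level relative to this one.
_REFERENCE_LEVEL = {
    "thermoregulation": "ectotherm",
    "diluent": "carbohydrate_free",
    "fertilization_mode": "external",
}

_RESPONSES = ("ejaculate_rate", "per_capita_rate")
_ESTIMATIONS = ("ML", "REML")


@dataclass
class ModelSpec:
    """What to fit: response scale, optional covariate, interaction,
    estimation mode."""

    response: str = "ejaculate_rate"
    covariate: Optional[str] = "thermoregulation"
    include_interaction: bool = False
    estimation: str = "REML"

    def validate(self) -> None:
        if self.response not in _RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.covariate is not None and self.covariate not in _REFERENCE_LEVEL:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.include_interaction and self.covariate is None:
            raise ValueError("an interaction requires a covariate")
        if self.estimation not in _ESTIMATIONS:
            raise ValueError(f"estimation must be one of {_ESTIMATIONS}")


@dataclass
class ReductionTrail:
    """Record of one likelihood-ratio reduction step (ML)."""

    lr_statistic: float
    df: int
    p_value: float
    delta_aic: float  # AIC(full) - AIC(reduced)
    interaction_retained: bool


@dataclass
class FitResult:
    """A fitted scaling model."""

    beta: float
    beta_se: float
    intercept: float
    intercept_se: float
    covariate_effect: Optional[float]
    covariate_se: Optional[float]
    interaction_effect: Optional[float]
    interaction_se: Optional[float]
    species_variance: float
    residual_variance: float
    loglik: float
    aic: float
    n_obs: int
    n_species: int
    n_fixed: int
    converged: bool
    at_boundary: bool  # species variance estimated at 0
    estimation: str
    spec: ModelSpec
    n_excluded: int = 0
    reduction: Optional[ReductionTrail] = None
    param_names: list[str] = field(default_factory=list)
    params: np.ndarray = field(default_factory=lambda: np.empty(0))
    cov_params: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


@dataclass
class WaldResult:
    """Wald t-test of the scaling exponent against a null value."""

    t_statistic: float
    df: int
    p_value: float
    null_value: float


@dataclass
class PerCapitaExponent:
    """Per-capita scaling exponent β − 1 with the SE of β carried over."""

    value: float
    se: float


def _design(dataset: Dataset, spec: ModelSpec, default_volume: float = 1.0):
    """Build y, X, species codes from the fit-eligible records."""
    recs = dataset.fit_records()
    n_excluded = len(dataset.records) - len(recs)
    if len(recs) < 3:
        raise ValueError(f"only {len(recs)} usable records; need at least 3")
    species = sorted({r.species for r in recs})
    sp_index = {s: i for i, s in enumerate(species)}
    groups = np.array([sp_index[r.species] for r in recs])

    if spec.response == "ejaculate_rate":
        y = np.array([math.log(r.rate) for r in recs])
    else:
        y = np.array([math.log(per_capita_rate(r, default_volume)) for r in recs])
    ln_c = np.array([math.log(r.concentration) for r in recs])

    cols = [np.ones(len(recs)), ln_c]
    names = ["intercept", "ln_concentration"]
    if spec.covariate is not None:
        ref = _REFERENCE_LEVEL[spec.covariate]
        x = np.array([0.0 if getattr(r, spec.covariate) == ref else 1.0 for r in recs])
        if x.min() == x.max():
            raise ValueError(
                f"covariate {spec.covariate!r} is constant in the data; singular design"
            )
        cols.append(x)
        names.append(spec.covariate)
        if spec.include_interaction:
            cols.append(x * ln_c)
            names.append(f"{spec.covariate}:ln_concentration")
    X = np.column_stack(cols)
    return y, X, groups, names, n_excluded


class _ProfileLikelihood:
    """Profile log-likelihood of the variance ratio θ = τ²/σ² for a
    random-intercept model, via per-group sufficient statistics.

    With V* = I + θ Z Zᵀ block diagonal over species, each species block
    inverse is I − θ/(1+θn_i) J, so XᵀV*⁻¹X, XᵀV*⁻¹y and yᵀV*⁻¹y are sums
    of per-group outer products — no n×n matrices are ever formed.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.group_sizes = np.bincount(groups)
        self.n_groups = self.group_sizes.size
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group within sums
        k = self.n_groups
        self.Xt1 = np.zeros((k, self.p))  # row g = sum of X rows in group g
        self.yt1 = np.zeros(k)
        np.add.at(self.Xt1, groups, X)
        np.add.at(self.yt1, groups, y)

    def gls(self, theta: float):
        """Closed-form GLS at a candidate θ: returns (beta, XtVX, rss, logdet)."""
        c = theta / (1.0 + theta * self.group_sizes)  # shrinkage per group
        XtVX = self.XtX - (self.Xt1 * c[:, None]).T @ self.Xt1
        XtVy = self.Xty - self.Xt1.T @ (c * self.yt1)
        ytVy = self.yty - float(c @ (self.yt1**2))
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)
        logdet = float(np.sum(np.log1p(theta * self.group_sizes)))
        return beta, XtVX, max(rss, 1e-300), logdet

    def loglik(self, theta: float, reml: bool) -> float:
        _, XtVX, rss, logdet = self.gls(theta)
        n, p = self.n, self.p
        if reml:
            dof = n - p
            sigma2 = rss / dof
            sign, ld_x = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return -np.inf
            return -0.5 * (dof * (math.log(2 * math.pi * sigma2) + 1.0) + logdet + ld_x)
        sigma2 = rss / n
        return -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)


def _fit_profiled(y, X, groups, reml: bool):
    prof = _ProfileLikelihood(y, X, groups)

    def negll(log_theta: float) -> float:
        return -prof.loglik(math.exp(log_theta), reml)

    # coarse deterministic grid over log θ, then bounded local refinement
    grid = np.linspace(-10.0, 8.0, 121)
    vals = np.array([negll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    theta = math.exp(res.x)
    best_ll = -res.fun
    converged = bool(res.success)
    # compare against the exact boundary θ = 0 (no species variance)
    ll0 = prof.loglik(0.0, reml)
    at_boundary = ll0 >= best_ll - 1e-10
    if at_boundary:
        theta, best_ll = 0.0, ll0

    beta, XtVX, rss, _ = prof.gls(theta)
    dof = prof.n - prof.p if reml else prof.n
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(XtVX)
    return {
        "params": beta,
        "cov_params": cov,
        "theta": theta,
        "sigma2": sigma2,
        "tau2": theta * sigma2,
        "loglik": best_ll,
        "converged": converged,
        "at_boundary": at_boundary,
        "n": prof.n,
        "p": prof.p,
        "n_groups": prof.n_groups,
    }


def fit_scaling_model(dataset: Dataset, spec: ModelSpec | None = None) -> FitResult:
    """Fit ln(rate) ~ ln(concentration) (+ covariate ± interaction) with a
    species random intercept.

    Standardized records and records lacking a measured concentration are
    excluded (their count is reported on the result). AIC counts fixed
    effects plus the two variance components.
    """
    spec = spec or ModelSpec()
    spec.validate()
    if spec.response == "per_capita_rate":
        volumes = {
            r.assay_volume if r.assay_volume is not None else 1.0
            for r in dataset.fit_records()
        }
        if len(volumes) == 1:
            # Constant chamber volume: subtracting ln C and ln V from the
            # response is an exact reparameterization of the ejaculate-level
            # model (same residuals, same likelihood), so fit that model and
            # shift beta by exactly -1 and the intercept by -ln V.
            ej = fit_scaling_model(dataset, replace(spec, response="ejaculate_rate"))
            ln_v = math.log(next(iter(volumes)))
            j_beta = ej.param_names.index("ln_concentration")
            j_int = ej.param_names.index("intercept")
            params = ej.params.copy()
            params[j_beta] -= 1.0
            params[j_int] -= ln_v
            return replace(
                ej,
                beta=ej.beta - 1.0,
                intercept=ej.intercept - ln_v,
                spec=spec,
                params=params,
            )
    y, X, groups, names, n_excluded = _design(dataset, spec)
    fit = _fit_profiled(y, X, groups, reml=(spec.estimation == "REML"))

    params = fit["params"]
    se = np.sqrt(np.diag(fit["cov_params"]))
    idx = {name: j for j, name in enumerate(names)}
    k = fit["p"] + 2  # fixed effects + species and residual variances
    cov_eff = cov_se = int_eff = int_se = None
    if spec.covariate is not None:
        j = idx[spec.covariate]
        cov_eff, cov_se = float(params[j]), float(se[j])
        if spec.include_interaction:
            j = idx[f"{spec.covariate}:ln_concentration"]
            int_eff, int_se = float(params[j]), float(se[j])
    return FitResult(
        beta=float(params[idx["ln_concentration"]]),
        beta_se=float(se[idx["ln_concentration"]]),
        intercept=float(params[idx["intercept"]]),
        intercept_se=float(se[idx["intercept"]]),
        covariate_effect=cov_eff,
        covariate_se=cov_se,
        interaction_effect=int_eff,
        interaction_se=int_se,
        species_variance=float(fit["tau2"]),
        residual_variance=float(fit["sigma2"]),
        loglik=float(fit["loglik"]),
        aic=2.0 * k - 2.0 * float(fit["loglik"]),
        n_obs=int(fit["n"]),
        n_species=int(fit["n_groups"]),
        n_fixed=int(fit["p"]),
        converged=bool(fit["converged"]),
        at_boundary=bool(fit["at_boundary"]),
        estimation=spec.estimation,
        spec=spec,
        n_excluded=n_excluded,
        param_names=names,
        params=np.asarray(params),
        cov_params=np.asarray(fit["cov_params"]),
    )


def model_reduction(
    dataset: Dataset, spec: ModelSpec, alpha: float = 0.05
) -> FitResult:
    """Multistep reduction: ML likelihood-ratio test of the
    covariate×concentration interaction, dropped when p > alpha; the
    selected model is refit under the requested estimation mode with the
    reduction trail attached."""
    spec.validate()
    if not spec.include_interaction:
        raise ValueError("model_reduction requires a spec with an interaction")
    ml_full = fit_scaling_model(dataset, replace(spec, estimation="ML"))
    ml_reduced = fit_scaling_model(
        dataset, replace(spec, include_interaction=False, estimation="ML")
    )
    lr = max(2.0 * (ml_full.loglik - ml_reduced.loglik), 0.0)
    p_value = float(stats.chi2.sf(lr, df=1))
    trail = ReductionTrail(
        lr_statistic=float(lr),
        df=1,
        p_value=p_value,
        delta_aic=float(ml_full.aic - ml_reduced.aic),
        interaction_retained=p_value <= alpha,
    )
    selected_spec = spec if trail.interaction_retained else replace(
        spec, include_interaction=False
    )
    final = fit_scaling_model(dataset, selected_spec)
    final.reduction = trail
    return final


def wald_test(fit: FitResult, null_value: float = 1.0) -> WaldResult:
    """Wald t-test of the concentration exponent against ``null_value``
    (1 = per-capita metabolism independent of density).

    Degrees of freedom are residual: n_obs − number of fixed-effect
    parameters.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; Wald test unavailable")
    if not (fit.beta_se > 0):
        raise ValueError("zero standard error for the exponent")
    t = (fit.beta - null_value) / fit.beta_se
    df = fit.n_obs - fit.n_fixed
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WaldResult(t_statistic=float(t), df=int(df), p_value=p, null_value=null_value)


def per_capita_exponent(fit: FitResult) -> PerCapitaExponent:
    """Per-capita exponent implied by an ejaculate-level fit: β − 1, with
    β's standard error unchanged (subtracting a constant shifts, never
    scales, the sampling distribution)."""
    if fit.spec is not None and fit.spec.response != "ejaculate_rate":
        raise ValueError("per_capita_exponent expects an ejaculate-level fit")
    return PerCapitaExponent(value=fit.beta - 1.0, se=fit.beta_se)
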