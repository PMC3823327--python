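"""Joint probability model for prevalence interpolation with collateral data.

Three observation streams are modelled jointly:

* source-frame prevalence counts  y_i ~ Poisson(E_i rho_i),
  log rho_i = beta1 + beta2 X_L(s_i) + z1(s_i) + e_i;
* target-frame hospitalisation counts  M_k ~ Poisson(G_k nu_k),
  log nu_k = gamma1 + gamma2 rho_k  (relative prevalence on the natural
  scale), with log rho_k = beta1 + beta2 x_k + z1(t_k) + e_k;
* target-frame log air quality  x_k ~ Normal(eta1 + z2(t_k), var_x).

z1 (prevalence process) and z2 (risk-factor process) are discrete process
convolutions over a shared grid, z(s) = sum_j kappa(|s-u_j|) w_j, with grid
effects w drawn from a normal or Student-t process.  The risk-factor process
interpolates the covariate to source areas as X_L(s_i) = eta1 + z2(s_i),
deterministic given (eta1, w2).  Residuals e are heteroscedastic with
log V = delta1 + delta2 * (E / offset_scale); over-dispersion beyond Poisson
is carried by e.

Priors: Normal(coeff_mean, coeff_variance) on beta, gamma, delta, eta1;
Gamma(shape, rate) on the precisions 1/var_w1, 1/var_w2, 1/var_x; the grid
process density (normal or t) on w; Normal(0, V) on residuals.

Latent target-frame prevalence counts carry no likelihood term: they would be
Poisson(E_k rho_k) draws adding no information beyond rho_k, and are exposed
only as a posterior-predictive convenience elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .frames import AreaFrame
from .kernels import Grid, KernelSpec, kernel_matrix

__all__ = [
    "ProcessSpec",
    "PriorSpec",
    "ModelSpec",
    "ParamState",
    "model_variant",
    "convolve_field",
    "latent_covariate",
    "log_relative_risk",
    "residual_variance",
    "hospitalisation_log_risk",
    "loglik_poisson",
    "loglik_airquality",
    "log_prior",
    "joint_log_posterior",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ProcessSpec:
    """Distribution of the grid random effects w_j: normal or Student-t.

    ``df`` is the Student-t degrees of freedom nu; the fitted heavy-tailed
    variants use 5.  The t is parameterised as t(0, df, var): ``var`` is the
    squared scale, so df -> infinity recovers Normal(0, var).
    """

    family: str = "normal"
    df: float = 5.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "student_t"):
            raise ValueError("process family must be 'normal' or 'student_t'")
        if not (self.df > 0):
            raise ValueError("process df must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the diffuse priors.

    Gamma(precision_shape, precision_rate) on every precision and
    Normal(coeff_mean, coeff_variance) on the regression coefficients
    beta, gamma, delta and eta1.  Defaults are the conventional diffuse
    choices: Gamma(0.001, 0.001) and Normal(0, 1000).
    """

    precision_shape: float = 0.001
    precision_rate: float = 0.001
    coeff_mean: float = 0.0
    coeff_variance: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.precision_shape > 0 and self.precision_rate > 0):
            raise ValueError("Gamma prior shape and rate must be positive")
        if not (self.coeff_variance > 0):
            raise ValueError("coefficient prior variance must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """One kernel/process variant plus priors.

    The four fitted variants are (normal | exponential kernel) x
    (normal | t5 process); the covariate enters log rho linearly (the only
    fitted form).
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    process: ProcessSpec = field(default_factory=ProcessSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    covariate_effect: str = "linear"

    def __post_init__(self) -> None:
        if self.covariate_effect != "linear":
            raise ValueError("only a linear covariate effect is implemented")


def model_variant(number: int, priors: PriorSpec | None = None) -> ModelSpec:
    """The four standard variants: 1 normal/normal, 2 exponential/normal,
    3 normal/t5, 4 exponential/t5 (standard kernels, scale 1)."""
    table = {
        1: ("normal", "normal"),
        2: ("exponential", "normal"),
        3: ("normal", "student_t"),
        4: ("exponential", "student_t"),
    }
    if number not in table:
        raise ValueError("model variant must be 1, 2, 3 or 4")
    kfam, pfam = table[number]
    return ModelSpec(
        kernel=KernelSpec(family=kfam, scale=1.0),
        process=ProcessSpec(family=pfam, df=5.0),
        priors=priors or PriorSpec(),
    )


@dataclass
class ParamState:
    """One value of all unknowns.

    beta = (intercept, pollution effect); gamma = (hospitalisation intercept,
    reflexive prevalence effect); delta = (log-variance intercept, slope);
    eta1 = risk-factor process mean; w1/w2 = grid effects of the prevalence
    and risk-factor processes; e_source/e_target = area residuals; var_w1,
    var_w2, var_x = grid-process and air-quality observation variances.
    """

    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    eta1: float
    w1: np.ndarray
    w2: np.ndarray
    e_source: np.ndarray
    e_target: np.ndarray
    var_w1: float = 1.0
    var_w2: float = 1.0
    var_x: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        for name in ("beta", "gamma", "delta"):
            if getattr(self, name).shape != (2,):
                raise ValueError(f"{name} must have length 2")
        for name in ("w1", "w2", "e_source", "e_target"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.var_w1 > 0 and self.var_w2 > 0 and self.var_x > 0):
            raise ValueError("variances must be positive")

    def validate(self, n_source: int, n_target: int, n_grid: int) -> None:
        if self.w1.shape != (n_grid,) or self.w2.shape != (n_grid,):
            raise ValueError("grid-effect vectors must have length J")
        if self.e_source.shape != (n_source,):
            raise ValueError("e_source must have length N")
        if self.e_target.shape != (n_target,):
            raise ValueError("e_target must have length K")

    def copy(self) -> "ParamState":
        return ParamState(
            beta=self.beta.copy(), gamma=self.gamma.copy(), delta=self.delta.copy(),
            eta1=self.eta1, w1=self.w1.copy(), w2=self.w2.copy(),
            e_source=self.e_source.copy(), e_target=self.e_target.copy(),
            var_w1=self.var_w1, var_w2=self.var_w2, var_x=self.var_x,
        )


# ---------------------------------------------------------------------------
# model components


def convolve_field(w: np.ndarray, kmat: np.ndarray) -> np.ndarray:
    """z(p) = sum_j kmat[p, j] w_j — the discrete process convolution."""
    w = np.asarray(w, dtype=float)
    kmat = np.asarray(kmat, dtype=float)
    if kmat.ndim != 2 or kmat.shape[1] != w.shape[0]:
        raise ValueError("kernel matrix columns must match the grid-effect length")
    return kmat @ w


def latent_covariate(eta1: float, z2_source: np.ndarray) -> np.ndarray:
    """Interpolated covariate at source centroids: X_L_i = eta1 + z2(s_i)."""
    return eta1 + np.asarray(z2_source, dtype=float)


def log_relative_risk(beta, covariate, z1, e) -> np.ndarray:
    """log rho = beta1 + beta2 * covariate + z1 + e."""
    beta = np.asarray(beta, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    z1 = np.asarray(z1, dtype=float)
    e = np.asarray(e, dtype=float)
    if not (covariate.shape == z1.shape == e.shape):
        raise ValueError("covariate, field and residual lengths must match")
    out = beta[0] + beta[1] * covariate + z1 + e
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite log relative risk")
    return out


def residual_variance(delta, offset, offset_scale: float | None = None) -> np.ndarray:
    """Heteroscedastic residual variances: log V = delta1 + delta2*(E/scale).

    ``offset_scale`` defaults to the mean offset of the frame, so delta2
    measures the log-variance change per mean-sized expected count.
    """
    delta = np.asarray(delta, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if np.any(offset <= 0):
        raise ValueError("offsets must be positive")
    if offset_scale is None:
        offset_scale = float(offset.mean())
    return np.exp(delta[0] + delta[1] * offset / offset_scale)


def hospitalisation_log_risk(gamma, rho_target) -> np.ndarray:
    """log nu_k = gamma1 + gamma2 * rho_k, rho on the natural scale."""
    gamma = np.asarray(gamma, dtype=float)
    rho = np.asarray(rho_target, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("relative prevalence must be positive")
    return gamma[0] + gamma[1] * rho


def loglik_poisson(count, mean) -> float:
    """Poisson log likelihood including the log(count!) normaliser."""
    count = np.asarray(count, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0) or not np.all(np.isfinite(mean)):
        raise ValueError("Poisson means must be positive and finite")
    return float(np.sum(count * np.log(mean) - mean - gammaln(count + 1.0)))


def loglik_airquality(x, mu, var_x: float) -> float:
    """Gaussian log likelihood of the observed covariate given its field mean."""
    if not (var_x > 0):
        raise ValueError("var_x must be positive")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = x - mu
    return float(-0.5 * (x.size * (LOG_2PI + math.log(var_x)) + np.sum(r * r) / var_x))


# ---------------------------------------------------------------------------
# prior and posterior


def _normal_logpdf(x, var) -> float:
    x = np.asarray(x, dtype=float)
    var = np.asarray(var, dtype=float)
    return float(np.sum(-0.5 * (LOG_2PI + np.log(var) + x * x / var)))


def _t_logpdf(x, df: float, var) -> float:
    # t(0, df, var): var is the squared scale.
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(
        n * (gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi))
        - 0.5 * np.sum(np.log(np.broadcast_to(var, x.shape)))
        - (df + 1) / 2 * np.sum(np.log1p(x * x / (df * var)))
    )


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * math.log(rate) - gammaln(shape) + (shape - 1) * math.log(x) - rate * x


def process_logpdf(w, spec: ProcessSpec, var: float) -> float:
    """Log density of grid effects under the configured process."""
    if spec.family == "normal":
        return _normal_logpdf(w, var)
    return _t_logpdf(w, spec.df, var)


def log_prior(state: ParamState, spec: ModelSpec, source: AreaFrame, target: AreaFrame,
              offset_scale_source: float | None = None,
              offset_scale_target: float | None = None) -> float:
    """Joint log prior of one parameter state.

    Gamma terms are evaluated at the precisions (1/var); the frames are
    needed because the residual priors Normal(0, V) depend on the expected
    counts through the log-variance regression.
    """
    pr = spec.priors
    coeffs = np.concatenate([state.beta, state.gamma, state.delta, [state.eta1]])
    lp = _normal_logpdf(coeffs - pr.coeff_mean, pr.coeff_variance)
    lp += process_logpdf(state.w1, spec.process, state.var_w1)
    lp += process_logpdf(state.w2, spec.process, state.var_w2)
    Vs = residual_variance(state.delta, source.offset_prevalence, offset_scale_source)
    Vt = residual_variance(state.delta, target.offset_prevalence, offset_scale_target)
    lp += _normal_logpdf(state.e_source, Vs)
    lp += _normal_logpdf(state.e_target, Vt)
    for v in (state.var_w1, state.var_w2, state.var_x):
        lp += _gamma_logpdf(1.0 / v, pr.precision_shape, pr.precision_rate)
    return lp


def joint_log_posterior(state: ParamState, source: AreaFrame, target: AreaFrame,
                        grid: Grid, spec: ModelSpec) -> float:
    """Unnormalised joint log posterior over all three observation streams.

    Sum of the source prevalence Poisson log likelihood, the target
    hospitalisation Poisson log likelihood, the air-quality Gaussian log
    likelihood and the log prior.  The source-frame regression uses the
    interpolated covariate X_L; the target-frame regression uses the observed
    covariate x_k.
    """
    state.validate(source.n, target.n, grid.n_points)
    if target.covariate is None or target.offset_morbidity is None:
        raise ValueError("target frame must carry covariate and morbidity offset")
    ks = kernel_matrix(source.centroids, grid, spec.kernel)
    kt = kernel_matrix(target.centroids, grid, spec.kernel)
    z1_s = convolve_field(state.w1, ks)
    z1_t = convolve_field(state.w1, kt)
    z2_s = convolve_field(state.w2, ks)
    z2_t = convolve_field(state.w2, kt)
    x_lat = latent_covariate(state.eta1, z2_s)
    log_rho_s = log_relative_risk(state.beta, x_lat, z1_s, state.e_source)
    log_rho_t = log_relative_risk(state.beta, target.covariate, z1_t, state.e_target)
    rho_t = np.exp(log_rho_t)
    log_nu = hospitalisation_log_risk(state.gamma, rho_t)
    nu = np.exp(log_nu)
    if not np.all(np.isfinite(nu)):
        return -np.inf
    ll = loglik_poisson(source.count, source.offset_prevalence * np.exp(log_rho_s))
    ll += loglik_poisson(target.count, target.offset_morbidity * nu)
    mu_x = state.eta1 + z2_t
    ll += loglik_airquality(target.covariate, mu_x, state.var_x)
    return ll + log_prior(state, spec, source, target)
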