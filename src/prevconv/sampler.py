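"""Adaptive Metropolis-within-Gibbs estimation of the joint posterior.

The sampler sweeps over parameter blocks: scalar random-walk updates for the
regression coefficients (beta, gamma, delta, eta1), single-site updates for
the grid effects w1 and w2 (with incremental updates of the cached fields, so
a site update costs O(N + K)), vectorised independent-site updates for the
residual vectors e, and conjugate Gibbs draws for the precisions whose full
conditionals are Gamma (normal-process grid variances and the air-quality
observation variance); under a Student-t process the grid precisions move by
random walk on the log scale instead.

The posterior has several soft directions (intercepts vs field means, the
coefficient pairs within each regression, covariate effects vs the field
pattern, gamma2 vs the overall risk level) that single-site sweeps cross
very slowly.  A set of dedicated joint Metropolis moves traverses them:
ridge moves pairing a coefficient with its compensating field/residual
change, global shift and rescale moves for each w vector, a block move in
the low-singular-value subspace of the stacked kernel matrix, and a
near-conjugate independence update of w2 driven by the Gaussian x-stream.
All are exact MH moves and leave the target invariant; docs/methods.md
derives each one.

Proposal scales adapt by a diminishing Robbins-Monro recursion on the log
scale toward a target acceptance rate during burn-in, then freeze, so the
retained draws come from a fixed-kernel chain.  Per-chain seeds derive from
the master seed via numpy SeedSequence spawning; identical inputs give
bitwise-identical draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assessment import gaussian_deviance, poisson_deviance
from .frames import AreaFrame
from .kernels import Grid, kernel_matrix
from .model import ModelSpec, ParamState, joint_log_posterior

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "initial_state",
    "run_mcmc",
    "gelman_rubin",
    "poisson_gamma_exceedance",
]

STRUCTURAL_PARAMS = (
    "beta1", "beta2", "gamma1", "gamma2", "delta1", "delta2", "eta1",
    "var_w1", "var_w2", "var_x",
)


@dataclass(frozen=True)
class ChainConfig:
    """Run-length, seeding and adaptation settings for one MCMC run."""

    n_chains: int = 2
    n_iter: int = 5000
    burn_fraction: float = 0.5
    thin: int = 1
    seed: int = 0
    adapt_iters: int | None = None  # defaults to the burn-in length
    target_accept: float = 0.44
    freeze_iters: int | None = None  # e_target frozen for this many initial
    # iterations (None: half the burn-in); see run_mcmc

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0.0 < self.burn_fraction < 1.0):
            raise ValueError("burn_fraction must be in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must be in (0, 1)")

    @property
    def n_burn(self) -> int:
        return int(round(self.burn_fraction * self.n_iter))

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class PosteriorDraws:
    """Retained draws from all chains plus derived per-draw fields.

    Scalar parameters are (n_chains, n_draws) arrays in ``structural``;
    grid effects are (n_chains, n_draws, J); the derived relative risks
    rho_source/rho_target, hospitalisation risks nu and air-quality means
    mu_x are stored per draw, as are the three stream deviances.
    """

    structural: dict[str, np.ndarray]
    w1: np.ndarray
    w2: np.ndarray
    rho_source: np.ndarray
    rho_target: np.ndarray
    nu: np.ndarray
    mu_x: np.ndarray
    deviance_y: np.ndarray
    deviance_m: np.ndarray
    deviance_x: np.ndarray
    acceptance: dict[str, float]
    config: ChainConfig
    spec: ModelSpec
    final_states: list[ParamState] | None = None

    @property
    def n_chains(self) -> int:
        return self.w1.shape[0]

    @property
    def n_draws(self) -> int:
        return self.w1.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: scalar params -> (C*D,), fields -> (C*D, P)."""
        if name in self.structural:
            return self.structural[name].reshape(-1)
        arr = getattr(self, name)
        return arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.reshape(-1)

    def structural_frame(self) -> pd.DataFrame:
        """Wide data frame of structural draws keyed by (chain, iteration)."""
        c, d = self.n_chains, self.n_draws
        out = {
            "chain": np.repeat(np.arange(c), d),
            "iteration": np.tile(np.arange(d), c),
        }
        for name in STRUCTURAL_PARAMS:
            out[name] = self.structural[name].reshape(-1)
        return pd.DataFrame(out)

    def summary(self, probs=(0.025, 0.05, 0.5, 0.95, 0.975)) -> pd.DataFrame:
        rows = []
        for name in STRUCTURAL_PARAMS:
            x = self.stacked(name)
            row = {"parameter": name, "mean": x.mean(), "sd": x.std(ddof=1)}
            for p in probs:
                row[f"q{100 * p:g}"] = np.quantile(x, p)
            rows.append(row)
        return pd.DataFrame(rows)


def initial_state(source: AreaFrame, target: AreaFrame, grid: Grid,
                  spec: ModelSpec, seed: int) -> ParamState:
    """Deterministic-in-seed start: coefficients 0, small random fields,
    unit variances; the joint posterior is finite here."""
    rng = np.random.default_rng(seed)
    j = grid.n_points
    return ParamState(
        beta=np.zeros(2), gamma=np.zeros(2), delta=np.zeros(2), eta1=0.0,
        w1=rng.normal(0.0, 0.1, j), w2=rng.normal(0.0, 0.1, j),
        e_source=rng.normal(0.0, 0.1, source.n), e_target=rng.normal(0.0, 0.1, target.n),
        var_w1=1.0, var_w2=1.0, var_x=1.0,
    )


def _check_init(state: ParamState, source, target, grid, spec) -> None:
    lp = joint_log_posterior(state, source, target, grid, spec)
    if not np.isfinite(lp):
        raise ValueError("joint log posterior non-finite at the initial state")


class _Adapt:
    """Robbins-Monro adaptation of log proposal scales (frozen after burn-in)."""

    def __init__(self, shape, init_log_scale: float, target: float):
        self.ls = np.full(shape, init_log_scale, dtype=float)
        self.target = target
        self.t = 0

    def step(self, accept_prob) -> None:
        self.t += 1
        gain = (self.t + 10.0) ** -0.6
        # bounded so a transient through a degenerate region cannot kill or
        # explode a proposal scale for the rest of the run
        self.ls = np.clip(self.ls + gain * (accept_prob - self.target),
                          math.log(1e-5), math.log(50.0))

    @property
    def scale(self):
        return np.exp(self.ls)


def _run_chain(data, spec: ModelSpec, config: ChainConfig, init: ParamState, seed) -> dict:
    """One chain.  ``data`` is the prepared dict of arrays and matrices.

    For the first ``freeze_iters`` iterations (all inside burn-in) the
    target-frame residual block is skipped, so the target-frame risk pattern
    comes from the shared field and the covariate.  That pattern identifies
    the sign basin of the reflexive effect gamma2 before the flexible
    residuals are released; without it, chains can lock into a spurious
    mirror basin (gamma2 of the wrong sign with inflated residuals) that has
    far lower posterior density but is locally sticky.  Burn-in-only
    intervention: retained draws come from the unmodified kernel.
    """
    rng = np.random.default_rng(seed)
    y, E = data["y"], data["E"]
    M, G = data["M"], data["G"]
    x = data["x"]
    Ks, Kt = data["Ks"], data["Kt"]
    Eh_s, Eh_t = data["Eh_s"], data["Eh_t"]
    s1, t1 = Ks.sum(axis=1), Kt.sum(axis=1)
    m1 = float((s1.sum() + t1.sum()) / (s1.size + t1.size))
    # least-squares ridge direction: v such that eta1 + z2 stays (almost)
    # flat when eta1 moves by d and w2 moves by d*v
    v_tgt = np.linalg.lstsq(Kt, -np.ones(Kt.shape[0]), rcond=None)[0]
    rs_tgt_x = 1.0 + Kt @ v_tgt     # residual change of mu_x per unit d
    rs_tgt_s = 1.0 + Ks @ v_tgt     # change of XL per unit d
    KsKs = Ks.T @ Ks
    # low-information subspace of w1: right singular vectors of the stacked
    # kernel matrix with below-median singular values; the likelihood barely
    # constrains these directions, so a dedicated block move lets the w1
    # amplitude (and with it var_w1) mix
    _, svals, vt_rows = np.linalg.svd(np.vstack([Ks, Kt]), full_matrices=True)
    n_low = max(1, vt_rows.shape[0] - np.searchsorted(-svals, -np.median(svals)))
    U_low = vt_rows[-n_low:].T
    KtKt = Kt.T @ Kt                # also used by the near-conjugate w2 block
    Kt_x = Kt.T @ x
    Ks_1 = Ks.sum(axis=0)
    Kt_1 = Kt.sum(axis=0)
    N, K, J = y.size, M.size, Ks.shape[1]
    eyeJ = np.eye(J)
    pr = spec.priors
    cvar = pr.coeff_variance
    cmean = pr.coeff_mean
    a0, b0 = pr.precision_shape, pr.precision_rate
    t_process = spec.process.family == "student_t"
    df = spec.process.df

    # --- state and caches -------------------------------------------------
    b1, b2 = float(init.beta[0]), float(init.beta[1])
    g1, g2 = float(init.gamma[0]), float(init.gamma[1])
    d1, d2 = float(init.delta[0]), float(init.delta[1])
    eta1 = float(init.eta1)
    w1 = init.w1.copy()
    w2 = init.w2.copy()
    es = init.e_source.copy()
    et = init.e_target.copy()
    lw1, lw2, lx = 1.0 / init.var_w1, 1.0 / init.var_w2, 1.0 / init.var_x

    z2s = Ks @ w2
    XL = eta1 + z2s
    log_rho_s = b1 + b2 * XL + Ks @ w1 + es
    rho_s = np.exp(log_rho_s)
    log_rho_t = b1 + b2 * x + Kt @ w1 + et
    rho_t = np.exp(log_rho_t)
    nu = np.exp(g1 + g2 * rho_t)
    mu_x = eta1 + Kt @ w2
    Vs = np.exp(d1 + d2 * Eh_s)
    Vt = np.exp(d1 + d2 * Eh_t)

    def coeff_dlp(old: float, d: float) -> float:
        return -0.5 * ((old + d - cmean) ** 2 - (old - cmean) ** 2) / cvar

    def w_prior_delta(w_old, d, lam):
        # change in grid-process log density when w_old -> w_old + d
        if t_process:
            return -(df + 1) / 2 * np.sum(
                np.log1p((w_old + d) ** 2 * lam / df) - np.log1p(w_old**2 * lam / df)
            )
        return -0.5 * lam * np.sum((w_old + d) ** 2 - w_old**2)

    # --- adaptation bookkeeping ------------------------------------------
    n_burn = config.n_burn
    adapt_iters = config.adapt_iters if config.adapt_iters is not None else n_burn
    adapt_iters = min(adapt_iters, n_burn)  # retained draws come from a frozen kernel
    freeze_iters = config.freeze_iters if config.freeze_iters is not None else n_burn // 2
    freeze_iters = min(freeze_iters, n_burn)
    tgt = config.target_accept
    # plain scalar blocks target 0.44 (univariate optimum); the joint
    # ridge/shift/rescale moves change many coordinates at once and target
    # a lower rate so post-freeze drift keeps them in a healthy band
    plain_names = ["beta1", "beta2", "gamma1", "gamma2", "delta1", "delta2", "eta1"]
    joint_names = ["beta_ridge", "b1_field", "b2_ridge", "gamma_ridge",
                   "gamma2_scale", "delta_ridge", "eta_field", "b1_ridge",
                   "eta_ridge", "w1_shift", "w1_scale", "w1_null",
                   "w2_shift", "w2_scale"]
    if t_process:
        plain_names += ["prec_w1", "prec_w2"]
    ad = {name: _Adapt((), math.log(0.1), tgt) for name in plain_names}
    ad.update({name: _Adapt((), math.log(0.1), min(tgt, 0.35)) for name in joint_names})
    ad["w2_block"] = _Adapt((), 0.0, tgt)  # independence proposal, no scale
    ad["w1"] = _Adapt(J, math.log(0.2), tgt)
    ad["w2"] = _Adapt(J, math.log(0.2), tgt)
    ad["e_source"] = _Adapt(N, math.log(0.2), tgt)
    ad["e_target"] = _Adapt(K, math.log(0.2), tgt)
    acc_count = {name: 0.0 for name in ad}
    acc_total = {name: 0.0 for name in ad}

    def bump(name, prob, adapting):
        # reported acceptance rates cover the post-adaptation phase only
        if not adapting:
            acc_count[name] += float(np.mean(prob))
            acc_total[name] += 1.0
        else:
            ad[name].step(prob)

    n_ret = config.n_retained
    store = {name: np.empty(n_ret) for name in STRUCTURAL_PARAMS}
    st_w1 = np.empty((n_ret, J))
    st_w2 = np.empty((n_ret, J))
    st_rho_s = np.empty((n_ret, N))
    st_rho_t = np.empty((n_ret, K))
    st_nu = np.empty((n_ret, K))
    st_mu_x = np.empty((n_ret, K))
    st_dev = np.empty((n_ret, 3))
    kept = 0

    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(config.n_iter):
            adapting = it < adapt_iters

            # ---- beta1 (both prevalence equations) -----------------------
            d = ad["beta1"].scale * rng.standard_normal()
            rho_s_n = rho_s * math.exp(d)
            rho_t_n = rho_t * math.exp(d)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            dlp = (np.sum(y) * d - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + coeff_dlp(b1, d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                b1 += d
                log_rho_s += d
                rho_s = rho_s_n
                log_rho_t += d
                rho_t = rho_t_n
                nu = nu_n
            bump("beta1", prob, adapting)

            # ---- beta2 (covariate effect) --------------------------------
            d = ad["beta2"].scale * rng.standard_normal()
            rho_s_n = rho_s * np.exp(d * XL)
            rho_t_n = rho_t * np.exp(d * x)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            dlp = (d * np.sum(y * XL) - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + coeff_dlp(b2, d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                b2 += d
                log_rho_s += d * XL
                rho_s = rho_s_n
                log_rho_t += d * x
                rho_t = rho_t_n
                nu = nu_n
            bump("beta2", prob, adapting)

            # ---- (beta1, beta2) ridge move -------------------------------
            # the likelihood constrains beta1 + beta2 * mean(covariate) much
            # more tightly than the pair itself; move along the soft direction
            # (XL is unchanged by the move, so the proposal is symmetric)
            d = ad["beta_ridge"].scale * rng.standard_normal()
            xbar = float(np.mean(XL))
            ls_shift = d * (XL - xbar)
            lt_shift = d * (x - xbar)
            rho_s_n = rho_s * np.exp(ls_shift)
            rho_t_n = rho_t * np.exp(lt_shift)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            dlp = (np.sum(y * ls_shift) - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + coeff_dlp(b2, d) + coeff_dlp(b1, -xbar * d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                b2 += d
                b1 -= xbar * d
                log_rho_s += ls_shift
                rho_s = rho_s_n
                log_rho_t += lt_shift
                rho_t = rho_t_n
                nu = nu_n
            bump("beta_ridge", prob, adapting)

            # ---- exact flat-direction moves for beta1 and beta2 ----------
            # shift the coefficient while w1 and the residuals absorb the
            # change exactly (log rho invariant, likelihood untouched); the
            # split between w1 and e minimises the total prior cost via a
            # small normal-equations solve.  The direction depends only on
            # quantities the move leaves fixed, so the proposal is symmetric.
            # clipped: the weights only shape the proposal direction, and
            # unbounded 1/V (deep in the small-variance funnel) would poison
            # the normal-equations solve
            ws_ = float(min(np.mean(1.0 / Vs), 1e4))
            wt_ = float(min(np.mean(1.0 / Vt), 1e4))
            Mmat = lw1 * eyeJ + ws_ * KsKs + wt_ * KtKt
            v_b1 = np.linalg.solve(Mmat, -(ws_ * Ks_1 + wt_ * Kt_1))
            r_s = 1.0 + Ks @ v_b1
            r_t = 1.0 + Kt @ v_b1
            # curvature-normalised step: Q depends only on quantities the
            # move leaves fixed (V, lw1, the direction), so the proposal
            # stays symmetric while tracking the drifting prior cost
            q_curv = (lw1 * np.sum(v_b1**2) + np.sum(r_s**2 / Vs)
                      + np.sum(r_t**2 / Vt) + 1.0 / cvar)
            d = ad["b1_ridge"].scale / math.sqrt(q_curv) * rng.standard_normal()
            dlp = (coeff_dlp(b1, d) + w_prior_delta(w1, d * v_b1, lw1)
                   - 0.5 * np.sum(((es - d * r_s) ** 2 - es**2) / Vs)
                   - 0.5 * np.sum(((et - d * r_t) ** 2 - et**2) / Vt))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                b1 += d
                w1 += d * v_b1
                es = es - d * r_s
                et = et - d * r_t
            bump("b1_ridge", prob, adapting)

            v_b2 = np.linalg.solve(Mmat, -(ws_ * (Ks.T @ XL) + wt_ * Kt_x))
            r_s = XL + Ks @ v_b2
            r_t = x + Kt @ v_b2
            q_curv = (lw1 * np.sum(v_b2**2) + np.sum(r_s**2 / Vs)
                      + np.sum(r_t**2 / Vt) + 1.0 / cvar)
            d = ad["b2_ridge"].scale / math.sqrt(q_curv) * rng.standard_normal()
            dlp = (coeff_dlp(b2, d) + w_prior_delta(w1, d * v_b2, lw1)
                   - 0.5 * np.sum(((es - d * r_s) ** 2 - es**2) / Vs)
                   - 0.5 * np.sum(((et - d * r_t) ** 2 - et**2) / Vt))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                b2 += d
                w1 += d * v_b2
                es = es - d * r_s
                et = et - d * r_t
            bump("b2_ridge", prob, adapting)

            # ---- gamma1, gamma2 (hospitalisation stream only) ------------
            d = ad["gamma1"].scale * rng.standard_normal()
            nu_n = nu * math.exp(d)
            dlp = np.sum(M) * d - np.sum(G * (nu_n - nu)) + coeff_dlp(g1, d)
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                g1 += d
                nu = nu_n
            bump("gamma1", prob, adapting)

            d = ad["gamma2"].scale * rng.standard_normal()
            nu_n = nu * np.exp(d * rho_t)
            dlp = d * np.sum(M * rho_t) - np.sum(G * (nu_n - nu)) + coeff_dlp(g2, d)
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                g2 += d
                nu = nu_n
            bump("gamma2", prob, adapting)

            # ---- (gamma1, gamma2) ridge move -----------------------------
            # log nu = gamma1 + gamma2 rho pins gamma1 + gamma2 * mean(rho);
            # rho_t is unchanged by the move, so the proposal is symmetric
            d = ad["gamma_ridge"].scale * rng.standard_normal()
            rbar = float(np.mean(rho_t))
            shift = d * (rho_t - rbar)
            nu_n = nu * np.exp(shift)
            dlp = (np.sum(M * shift) - np.sum(G * (nu_n - nu))
                   + coeff_dlp(g2, d) + coeff_dlp(g1, -rbar * d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                g2 += d
                g1 -= rbar * d
                nu = nu_n
            bump("gamma_ridge", prob, adapting)

            # ---- delta1, delta2 (residual-variance regression) -----------
            ss_s = np.sum(es**2 / Vs)
            ss_t = np.sum(et**2 / Vt)
            d = ad["delta1"].scale * rng.standard_normal()
            if rng.random() < 0.25:
                d *= 10.0  # occasional long jump across the flat tail
            dlp = (-0.5 * (N + K) * d - 0.5 * (math.exp(-d) - 1.0) * (ss_s + ss_t)
                   + coeff_dlp(d1, d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                d1 += d
                Vs *= math.exp(d)
                Vt *= math.exp(d)
            bump("delta1", prob, adapting)

            d = ad["delta2"].scale * rng.standard_normal()
            if rng.random() < 0.25:
                d *= 10.0  # occasional long jump across the flat tail
            Vs_n = Vs * np.exp(d * Eh_s)
            Vt_n = Vt * np.exp(d * Eh_t)
            dlp = (-0.5 * d * (np.sum(Eh_s) + np.sum(Eh_t))
                   - 0.5 * (np.sum(es**2 / Vs_n) + np.sum(et**2 / Vt_n) -
                            np.sum(es**2 / Vs) - np.sum(et**2 / Vt))
                   + coeff_dlp(d2, d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                d2 += d
                Vs, Vt = Vs_n, Vt_n
            bump("delta2", prob, adapting)

            # ---- eta1 (risk-factor process mean) -------------------------
            d = ad["eta1"].scale * rng.standard_normal()
            rho_s_n = rho_s * math.exp(b2 * d)
            r = x - mu_x
            dlp = (b2 * d * np.sum(y) - np.sum(E * (rho_s_n - rho_s))
                   + lx * (d * np.sum(r) - 0.5 * K * d * d)
                   + coeff_dlp(eta1, d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                eta1 += d
                XL = XL + d
                log_rho_s += b2 * d
                rho_s = rho_s_n
                mu_x = mu_x + d
            bump("eta1", prob, adapting)

            # ---- w1 single-site sweep ------------------------------------
            dws = ad["w1"].scale * rng.standard_normal(J)
            logu = np.log(rng.random(J))
            probs = np.empty(J)
            for j in range(J):
                d = dws[j]
                a_s = Ks[:, j] * d
                a_t = Kt[:, j] * d
                rho_s_n = rho_s * np.exp(a_s)
                rho_t_n = rho_t * np.exp(a_t)
                nu_n = np.exp(g1 + g2 * rho_t_n)
                dlp = (np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                       + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                       + w_prior_delta(w1[j], d, lw1))
                ok = np.isfinite(dlp)
                probs[j] = math.exp(min(0.0, dlp)) if ok else 0.0
                if ok and logu[j] < dlp:
                    w1[j] += d
                    log_rho_s += a_s
                    rho_s = rho_s_n
                    log_rho_t += a_t
                    rho_t = rho_t_n
                    nu = nu_n
            bump("w1", probs, adapting)

            # ---- w1 low-information subspace block -----------------------
            d = ad["w1_null"].scale * rng.standard_normal(U_low.shape[1])
            dw = U_low @ d
            a_s = Ks @ dw
            a_t = Kt @ dw
            rho_s_n = rho_s * np.exp(a_s)
            rho_t_n = rho_t * np.exp(a_t)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            dlp = (np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + w_prior_delta(w1, dw, lw1))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                w1 += dw
                log_rho_s += a_s
                rho_s = rho_s_n
                log_rho_t += a_t
                rho_t = rho_t_n
                nu = nu_n
            bump("w1_null", prob, adapting)

            # ---- w1 global shift -----------------------------------------
            d = ad["w1_shift"].scale * rng.standard_normal()
            a_s = s1 * d
            a_t = t1 * d
            rho_s_n = rho_s * np.exp(a_s)
            rho_t_n = rho_t * np.exp(a_t)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            dlp = (np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + w_prior_delta(w1, d, lw1))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                w1 += d
                log_rho_s += a_s
                rho_s = rho_s_n
                log_rho_t += a_t
                rho_t = rho_t_n
                nu = nu_n
            bump("w1_shift", prob, adapting)

            # ---- (beta1, w1) ridge: intercept vs prevalence-field mean ---
            # raise beta1 while lowering every w1 by d/m1 (m1 = mean kernel
            # row sum), leaving the fitted field nearly unchanged; fixed
            # direction, symmetric proposal
            d = ad["b1_field"].scale * rng.standard_normal()
            a_s = d * (1.0 - s1 / m1)
            a_t = d * (1.0 - t1 / m1)
            rho_s_n = rho_s * np.exp(a_s)
            rho_t_n = rho_t * np.exp(a_t)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            dlp = (np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + coeff_dlp(b1, d) + w_prior_delta(w1, -d / m1, lw1))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                b1 += d
                w1 -= d / m1
                log_rho_s += a_s
                rho_s = rho_s_n
                log_rho_t += a_t
                rho_t = rho_t_n
                nu = nu_n
            bump("b1_field", prob, adapting)

            # ---- w1 amplitude rescale (with the conjugate variance draw
            # this lets var_w1 traverse its ridge); log-scale proposal with
            # Jacobian J*d
            d = ad["w1_scale"].scale * rng.standard_normal()
            c = math.exp(d)
            a_s = (c - 1.0) * (Ks @ w1)
            a_t = (c - 1.0) * (Kt @ w1)
            rho_s_n = rho_s * np.exp(a_s)
            rho_t_n = rho_t * np.exp(a_t)
            nu_n = np.exp(g1 + g2 * rho_t_n)
            if t_process:
                dpr = -(df + 1) / 2 * np.sum(np.log1p(c * c * w1**2 * lw1 / df)
                                             - np.log1p(w1**2 * lw1 / df))
            else:
                dpr = -0.5 * lw1 * (c * c - 1.0) * np.sum(w1**2)
            dlp = (np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   + g2 * np.sum(M * (rho_t_n - rho_t)) - np.sum(G * (nu_n - nu))
                   + dpr + J * d)
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                w1 *= c
                log_rho_s += a_s
                rho_s = rho_s_n
                log_rho_t += a_t
                rho_t = rho_t_n
                nu = nu_n
            bump("w1_scale", prob, adapting)

            # ---- w2 single-site sweep ------------------------------------
            dws = ad["w2"].scale * rng.standard_normal(J)
            logu = np.log(rng.random(J))
            probs = np.empty(J)
            for j in range(J):
                d = dws[j]
                a_s = Ks[:, j] * d          # change in z2 at source centroids
                a_x = Kt[:, j] * d          # change in mu_x
                rho_s_n = rho_s * np.exp(b2 * a_s)
                mu_x_n = mu_x + a_x
                dlp = (b2 * np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                       - 0.5 * lx * (np.sum((x - mu_x_n) ** 2) - np.sum((x - mu_x) ** 2))
                       + w_prior_delta(w2[j], d, lw2))
                ok = np.isfinite(dlp)
                probs[j] = math.exp(min(0.0, dlp)) if ok else 0.0
                if ok and logu[j] < dlp:
                    w2[j] += d
                    z2s += a_s
                    XL = XL + a_s
                    log_rho_s += b2 * a_s
                    rho_s = rho_s_n
                    mu_x = mu_x_n
            bump("w2", probs, adapting)

            # ---- w2 global shift -----------------------------------------
            d = ad["w2_shift"].scale * rng.standard_normal()
            a_s = s1 * d
            a_x = t1 * d
            rho_s_n = rho_s * np.exp(b2 * a_s)
            mu_x_n = mu_x + a_x
            dlp = (b2 * np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   - 0.5 * lx * (np.sum((x - mu_x_n) ** 2) - np.sum((x - mu_x) ** 2))
                   + w_prior_delta(w2, d, lw2))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                w2 += d
                z2s += a_s
                XL = XL + a_s
                log_rho_s += b2 * a_s
                rho_s = rho_s_n
                mu_x = mu_x_n
            bump("w2_shift", prob, adapting)

            # ---- (eta1, w2) ridge: risk-factor mean vs field mean --------
            d = ad["eta_field"].scale * rng.standard_normal()
            a_s = d * (1.0 - s1 / m1)   # change in XL
            a_x = d * (1.0 - t1 / m1)   # change in mu_x
            rho_s_n = rho_s * np.exp(b2 * a_s)
            mu_x_n = mu_x + a_x
            dlp = (b2 * np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   - 0.5 * lx * (np.sum((x - mu_x_n) ** 2) - np.sum((x - mu_x) ** 2))
                   + coeff_dlp(eta1, d) + w_prior_delta(w2, -d / m1, lw2))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                eta1 += d
                w2 -= d / m1
                z2s += a_s - d
                XL = XL + a_s
                log_rho_s += b2 * a_s
                rho_s = rho_s_n
                mu_x = mu_x_n
            bump("eta_field", prob, adapting)

            # ---- w2 near-conjugate block update --------------------------
            # the x-stream likelihood in w2 is Gaussian; propose the whole
            # vector from the x-stream + normal-prior conditional and accept
            # with an MH correction for the y-stream coupling (and for the
            # process density when it is Student-t)
            P = lx * KtKt + lw2 * np.eye(J)
            L = np.linalg.cholesky(P)
            mvec = np.linalg.solve(P, lx * (Kt.T @ (x - eta1)))
            w2p = mvec + np.linalg.solve(L.T, rng.standard_normal(J))
            dXL = Ks @ (w2p - w2)
            mu_x_n = eta1 + Kt @ w2p
            rho_s_n = rho_s * np.exp(b2 * dXL)
            d_llx = -0.5 * lx * (np.sum((x - mu_x_n) ** 2) - np.sum((x - mu_x) ** 2))
            d_lly = b2 * np.sum(y * dXL) - np.sum(E * (rho_s_n - rho_s))
            if t_process:
                d_prior = -(df + 1) / 2 * np.sum(np.log1p(w2p**2 * lw2 / df)
                                                 - np.log1p(w2**2 * lw2 / df))
            else:
                d_prior = -0.5 * lw2 * (np.sum(w2p**2) - np.sum(w2**2))
            r_old = w2 - mvec
            r_new = w2p - mvec
            d_q = -0.5 * (r_old @ P @ r_old - r_new @ P @ r_new)
            dlp = d_llx + d_lly + d_prior + d_q
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                z2s += dXL
                XL = XL + dXL
                log_rho_s += b2 * dXL
                rho_s = rho_s_n
                mu_x = mu_x_n
                w2 = w2p
            bump("w2_block", prob, adapting)  # fixed-form proposal; stats only

            # ---- (eta1, w2) exact ridge: keeps mu_x nearly invariant so
            # the tight air-quality likelihood does not block the move
            d = ad["eta_ridge"].scale * rng.standard_normal()
            a_s = d * rs_tgt_s     # change in XL
            a_x = d * rs_tgt_x    # change in mu_x (near zero)
            rho_s_n = rho_s * np.exp(b2 * a_s)
            mu_x_n = mu_x + a_x
            dlp = (b2 * np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   - 0.5 * lx * (np.sum((x - mu_x_n) ** 2) - np.sum((x - mu_x) ** 2))
                   + coeff_dlp(eta1, d) + w_prior_delta(w2, d * v_tgt, lw2))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                eta1 += d
                w2 += d * v_tgt
                z2s += a_s - d
                XL = XL + a_s
                log_rho_s += b2 * a_s
                rho_s = rho_s_n
                mu_x = mu_x_n
            bump("eta_ridge", prob, adapting)

            # ---- w2 amplitude rescale ------------------------------------
            d = ad["w2_scale"].scale * rng.standard_normal()
            c = math.exp(d)
            a_s = (c - 1.0) * z2s
            a_x = (c - 1.0) * (Kt @ w2)
            rho_s_n = rho_s * np.exp(b2 * a_s)
            mu_x_n = mu_x + a_x
            if t_process:
                dpr = -(df + 1) / 2 * np.sum(np.log1p(c * c * w2**2 * lw2 / df)
                                             - np.log1p(w2**2 * lw2 / df))
            else:
                dpr = -0.5 * lw2 * (c * c - 1.0) * np.sum(w2**2)
            dlp = (b2 * np.sum(y * a_s) - np.sum(E * (rho_s_n - rho_s))
                   - 0.5 * lx * (np.sum((x - mu_x_n) ** 2) - np.sum((x - mu_x) ** 2))
                   + dpr + J * d)
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                w2 *= c
                z2s += a_s
                XL = XL + a_s
                log_rho_s += b2 * a_s
                rho_s = rho_s_n
                mu_x = mu_x_n
            bump("w2_scale", prob, adapting)

            # ---- (gamma2, rho level) exact trade-off ---------------------
            # gamma2 * rho is what the hospitalisation stream sees; rescale
            # gamma2 while shifting every target residual by the matching
            # constant so nu is exactly invariant (translation map, unit
            # Jacobian; rejected if the proposal would flip gamma2's sign)
            inv_vt_sum = float(np.sum(1.0 / Vt))

            def g2_curv(g):
                return 1.0 / cvar + inv_vt_sum / (g * g)

            if g2 != 0.0:
                q_old = g2_curv(g2)
                d = ad["gamma2_scale"].scale / math.sqrt(q_old) * rng.standard_normal()
            else:
                q_old = 1.0
                d = 0.0
            if g2 != 0.0 and (g2 + d) * g2 > 0.0:
                c = math.log(g2 / (g2 + d))
                # the curvature moves with gamma2, so the proposal is not
                # symmetric; the Hastings term compares forward and reverse
                # proposal densities at the matched displacement
                q_new = g2_curv(g2 + d)
                s2 = float(ad["gamma2_scale"].scale) ** 2
                hastings = 0.5 * math.log(q_new / q_old) - (q_new - q_old) * d * d / (2.0 * s2)
                dlp = (coeff_dlp(g2, d)
                       - 0.5 * np.sum(((et + c) ** 2 - et**2) / Vt)
                       + hastings)
                prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
                if rng.random() < prob:
                    g2 += d
                    et = et + c
                    log_rho_t += c
                    rho_t = rho_t * math.exp(c)
                bump("gamma2_scale", prob, adapting)
            elif not adapting:
                # structural rejection (sign flip): counts against the
                # acceptance rate but must not shrink the adapted scale
                bump("gamma2_scale", 0.0, False)

            # ---- (delta1, delta2) ridge ----------------------------------
            # scaled offsets average one, so the likelihood-relevant log
            # variances pin delta1 + delta2 while the difference is flat;
            # move along the flat direction
            d = ad["delta_ridge"].scale * rng.standard_normal()
            if rng.random() < 0.25:
                d *= 10.0  # occasional long jump across the flat tail
            dv_s = d * (Eh_s - 1.0)
            dv_t = d * (Eh_t - 1.0)
            dlp = (-0.5 * (np.sum(dv_s) + np.sum(dv_t))
                   - 0.5 * (np.sum(es**2 / Vs * np.expm1(-dv_s))
                            + np.sum(et**2 / Vt * np.expm1(-dv_t)))
                   + coeff_dlp(d2, d) + coeff_dlp(d1, -d))
            prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
            if rng.random() < prob:
                d2 += d
                d1 -= d
                Vs = Vs * np.exp(dv_s)
                Vt = Vt * np.exp(dv_t)
            bump("delta_ridge", prob, adapting)

            # ---- residual vectors (independent sites, vectorised) --------
            d = ad["e_source"].scale * rng.standard_normal(N)
            rho_s_n = rho_s * np.exp(d)
            dlp = y * d - E * (rho_s_n - rho_s) - 0.5 * ((es + d) ** 2 - es**2) / Vs
            prob = np.exp(np.minimum(0.0, np.where(np.isfinite(dlp), dlp, -np.inf)))
            acc = rng.random(N) < prob
            es = np.where(acc, es + d, es)
            log_rho_s = np.where(acc, log_rho_s + d, log_rho_s)
            rho_s = np.where(acc, rho_s_n, rho_s)
            bump("e_source", prob, adapting)

            if it >= freeze_iters:
                d = ad["e_target"].scale * rng.standard_normal(K)
                rho_t_n = rho_t * np.exp(d)
                nu_n = np.exp(g1 + g2 * rho_t_n)
                dlp = (g2 * M * (rho_t_n - rho_t) - G * (nu_n - nu)
                       - 0.5 * ((et + d) ** 2 - et**2) / Vt)
                prob = np.exp(np.minimum(0.0, np.where(np.isfinite(dlp), dlp, -np.inf)))
                acc = rng.random(K) < prob
                et = np.where(acc, et + d, et)
                log_rho_t = np.where(acc, log_rho_t + d, log_rho_t)
                rho_t = np.where(acc, rho_t_n, rho_t)
                nu = np.where(acc, nu_n, nu)
                bump("e_target", prob, adapting)

            # ---- precisions ----------------------------------------------
            if t_process:
                for name, wv in (("prec_w1", w1), ("prec_w2", w2)):
                    lam = lw1 if name == "prec_w1" else lw2
                    d = ad[name].scale * rng.standard_normal()
                    lam_n = lam * math.exp(d)
                    # Gamma prior + t process likelihood + log-scale Jacobian
                    dlp = (a0 * d - b0 * (lam_n - lam)
                           + 0.5 * J * d
                           - (df + 1) / 2 * np.sum(np.log1p(wv**2 * lam_n / df)
                                                   - np.log1p(wv**2 * lam / df)))
                    prob = math.exp(min(0.0, dlp)) if np.isfinite(dlp) else 0.0
                    if rng.random() < prob:
                        if name == "prec_w1":
                            lw1 = lam_n
                        else:
                            lw2 = lam_n
                    bump(name, prob, adapting)
            else:
                lw1 = rng.gamma(a0 + 0.5 * J, 1.0 / (b0 + 0.5 * np.sum(w1**2)))
                lw2 = rng.gamma(a0 + 0.5 * J, 1.0 / (b0 + 0.5 * np.sum(w2**2)))
            lx = rng.gamma(a0 + 0.5 * K, 1.0 / (b0 + 0.5 * np.sum((x - mu_x) ** 2)))

            # ---- storage -------------------------------------------------
            if it >= n_burn and (it - n_burn) % config.thin == 0 and kept < n_ret:
                for name, val in (("beta1", b1), ("beta2", b2), ("gamma1", g1),
                                  ("gamma2", g2), ("delta1", d1), ("delta2", d2),
                                  ("eta1", eta1), ("var_w1", 1.0 / lw1),
                                  ("var_w2", 1.0 / lw2), ("var_x", 1.0 / lx)):
                    store[name][kept] = val
                st_w1[kept] = w1
                st_w2[kept] = w2
                st_rho_s[kept] = rho_s
                st_rho_t[kept] = rho_t
                st_nu[kept] = nu
                st_mu_x[kept] = mu_x
                # floor the means: nu (or rho) may legitimately underflow to
                # zero for zero-count areas, where the deviance term is zero
                st_dev[kept, 0] = poisson_deviance(y, np.maximum(E * rho_s, 1e-300))
                st_dev[kept, 1] = poisson_deviance(M, np.maximum(G * nu, 1e-300))
                st_dev[kept, 2] = gaussian_deviance(x, mu_x, 1.0 / lx)
                kept += 1

    rates = {name: acc_count[name] / max(acc_total[name], 1.0) for name in acc_count}
    final = ParamState(
        beta=np.array([b1, b2]), gamma=np.array([g1, g2]), delta=np.array([d1, d2]),
        eta1=eta1, w1=w1.copy(), w2=w2.copy(), e_source=es.copy(), e_target=et.copy(),
        var_w1=1.0 / lw1, var_w2=1.0 / lw2, var_x=1.0 / lx,
    )
    return {
        "store": store, "w1": st_w1, "w2": st_w2, "rho_s": st_rho_s,
        "rho_t": st_rho_t, "nu": st_nu, "mu_x": st_mu_x, "dev": st_dev,
        "acceptance": rates, "final_state": final,
        "proposal_scales": {name: np.mean(a.scale) for name, a in ad.items()},
    }


def _prepare_data(source: AreaFrame, target: AreaFrame, grid: Grid, spec: ModelSpec) -> dict:
    if target.covariate is None or target.offset_morbidity is None:
        raise ValueError("target frame must carry covariate and morbidity offset")
    E = source.offset_prevalence
    Et = target.offset_prevalence
    return {
        "y": source.count.astype(float), "E": E,
        "M": target.count.astype(float), "G": target.offset_morbidity,
        "x": target.covariate,
        "Ks": kernel_matrix(source.centroids, grid, spec.kernel),
        "Kt": kernel_matrix(target.centroids, grid, spec.kernel),
        "Eh_s": E / E.mean(), "Eh_t": Et / Et.mean(),
    }


def run_mcmc(source: AreaFrame, target: AreaFrame, grid: Grid, spec: ModelSpec,
             config: ChainConfig) -> PosteriorDraws:
    """Run ``config.n_chains`` chains and return the retained draws.

    Deterministic: identical (data, spec, config) give identical output.
    Warns if any block's post-adaptation acceptance rate is zero.
    """
    if config.n_retained < 1:
        raise ValueError("configuration retains no draws")
    data = _prepare_data(source, target, grid, spec)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains + 1)
    results = []
    for c in range(config.n_chains):
        init = initial_state(source, target, grid, spec,
                             seed=np.random.default_rng(seeds[-1]).integers(2**31 - 1) + c)
        _check_init(init, source, target, grid, spec)
        results.append(_run_chain(data, spec, config, init, seeds[c]))

    structural = {
        name: np.stack([r["store"][name] for r in results]) for name in STRUCTURAL_PARAMS
    }
    acceptance = {
        name: float(np.mean([r["acceptance"][name] for r in results]))
        for name in results[0]["acceptance"]
    }
    for name, rate in acceptance.items():
        if rate == 0.0:
            warnings.warn(f"block {name!r} accepted no proposals", RuntimeWarning)
    dev = np.stack([r["dev"] for r in results])
    return PosteriorDraws(
        structural=structural,
        w1=np.stack([r["w1"] for r in results]),
        w2=np.stack([r["w2"] for r in results]),
        rho_source=np.stack([r["rho_s"] for r in results]),
        rho_target=np.stack([r["rho_t"] for r in results]),
        nu=np.stack([r["nu"] for r in results]),
        mu_x=np.stack([r["mu_x"] for r in results]),
        deviance_y=dev[:, :, 0], deviance_m=dev[:, :, 1], deviance_x=dev[:, :, 2],
        acceptance=acceptance, config=config, spec=spec,
        final_states=[r["final_state"] for r in results],
    )


def gelman_rubin(draws: PosteriorDraws | dict[str, np.ndarray],
                 params: list[str] | None = None) -> dict[str, float]:
    """Brooks-Gelman-Rubin potential scale reduction factors.

    For each selected scalar parameter with m >= 2 chains of n draws:
    W = mean within-chain variance, B/n = variance of chain means,
    Vhat = (n-1)/n W + (1 + 1/m) B/n, PSRF = sqrt(Vhat / W), floored at 1
    (values below 1 are sampling noise).  Degenerate chains (W = B = 0)
    give PSRF = 1.
    """
    if isinstance(draws, PosteriorDraws):
        series = {name: draws.structural[name] for name in (params or STRUCTURAL_PARAMS)}
    else:
        series = {k: np.asarray(v) for k, v in draws.items()
                  if params is None or k in params}
    out = {}
    for name, arr in series.items():
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("PSRF needs >= 2 chains of scalar draws")
        m, n = arr.shape
        if n < 2:
            raise ValueError("PSRF needs >= 2 draws per chain")
        within = float(np.mean(np.var(arr, axis=1, ddof=1)))
        b_over_n = float(np.var(np.mean(arr, axis=1), ddof=1))
        if within == 0.0:
            out[name] = 1.0 if b_over_n == 0.0 else float("inf")
            continue
        v_hat = (n - 1) / n * within + (1.0 + 1.0 / m) * b_over_n
        out[name] = max(1.0, math.sqrt(v_hat / within))
    return out


def poisson_gamma_exceedance(y: int, expected: float, prior_shape: float,
                             prior_rate: float, n_iter: int = 20000,
                             burn_fraction: float = 0.5, seed: int = 0,
                             target_accept: float = 0.44) -> tuple[float, float]:
    """Single-area conjugate subcase: y ~ Poisson(E rho), rho ~ Gamma(a, b).

    Runs the same adaptive random-walk Metropolis step used by the full
    sampler, on theta = log rho, and returns (MCMC estimate of Pr(rho > 1),
    exact posterior tail from the conjugate Gamma(a + y, b + E)).
    """
    rng = np.random.default_rng(seed)
    theta = 0.0
    ad = _Adapt((), math.log(0.5), target_accept)
    n_burn = int(round(burn_fraction * n_iter))
    exceed = 0
    kept = 0
    for it in range(n_iter):
        d = float(ad.scale) * rng.standard_normal()
        th_n = theta + d
        # target in theta: (a + y) theta - (b + E) e^theta  (prior + lik + Jacobian)
        dlp = (prior_shape + y) * d - (prior_rate + expected) * (math.exp(th_n) - math.exp(theta))
        prob = math.exp(min(0.0, dlp))
        if rng.random() < prob:
            theta = th_n
        if it < n_burn:
            ad.step(prob)
        else:
            kept += 1
            exceed += theta > 0.0
    exact = float(stats.gamma.sf(1.0, prior_shape + y, scale=1.0 / (prior_rate + expected)))
    return exceed / kept, exact
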