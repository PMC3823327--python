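"""Probability-model components and the joint log posterior."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, t as t_dist

import prevconv as pc
from prevconv.kernels import kernel_matrix
from prevconv.model import log_prior, process_logpdf

from conftest import toy_frames, toy_state


# ---------------------------------------------------------------------------
# component operations


def test_convolve_field_against_double_loop():
    rng = np.random.default_rng(0)
    kmat = rng.uniform(0, 1, size=(4, 3))
    w = rng.normal(size=3)
    expected = np.array([sum(kmat[p, j] * w[j] for j in range(3)) for p in range(4)])
    assert np.allclose(pc.convolve_field(w, kmat), expected)
    assert np.all(pc.convolve_field(np.zeros(3), kmat) == 0)
    assert np.allclose(pc.convolve_field(np.array([2.5]), np.ones((5, 1))), 2.5)


def test_convolve_field_dimension_mismatch():
    with pytest.raises(ValueError):
        pc.convolve_field(np.zeros(2), np.ones((3, 4)))


def test_latent_covariate_is_mean_of_risk_factor_process():
    assert np.all(pc.latent_covariate(0.0, np.zeros(4)) == 0)
    assert np.allclose(pc.latent_covariate(1.7, np.zeros(4)), 1.7)
    z = np.array([0.3, -0.2, 0.0])
    assert np.allclose(pc.latent_covariate(0.5, z), 0.5 + z)


def test_log_relative_risk_scalar_loop():
    rng = np.random.default_rng(1)
    beta = np.array([-0.4, 0.7])
    cov, z1, e = rng.normal(size=(3, 5))
    out = pc.log_relative_risk(beta, cov, z1, e)
    for i in range(5):
        assert out[i] == pytest.approx(beta[0] + beta[1] * cov[i] + z1[i] + e[i])
    assert np.all(pc.log_relative_risk([0, 0], np.zeros(3), np.zeros(3), np.zeros(3)) == 0)


def test_residual_variance_examples_and_monotonicity():
    offs = np.array([5.0, 10.0, 20.0, 80.0])
    assert np.allclose(pc.residual_variance([0.0, 0.0], offs), 1.0)
    assert np.allclose(pc.residual_variance([np.log(4.0), 0.0], offs), 4.0)
    v = pc.residual_variance([0.0, 0.5], offs)
    assert np.all(np.diff(v) > 0)  # larger expected counts, larger variance
    with pytest.raises(ValueError):
        pc.residual_variance([0.0, 0.1], np.array([1.0, -2.0]))


def test_hospitalisation_log_risk_natural_scale():
    rho = np.array([0.5, 1.0, 2.0])
    out = pc.hospitalisation_log_risk([-1.0, 1.0], rho)
    assert np.allclose(out, -1.0 + rho)  # rho enters untransformed
    assert out[1] == pytest.approx(0.0)
    assert np.all(pc.hospitalisation_log_risk([0.0, 0.0], rho) == 0)
    with pytest.raises(ValueError):
        pc.hospitalisation_log_risk([0.0, 1.0], np.array([1.0, -0.5]))


def test_loglik_poisson_closed_forms():
    assert pc.loglik_poisson([0], [1.0]) == pytest.approx(-1.0)
    assert pc.loglik_poisson([2], [2.0]) == pytest.approx(2 * math.log(2) - 2 - math.log(2))
    counts = np.array([3, 0, 7])
    means = np.array([2.5, 1.2, 6.0])
    total = pc.loglik_poisson(counts, means)
    parts = sum(pc.loglik_poisson([c], [m]) for c, m in zip(counts, means))
    assert total == pytest.approx(parts)
    with pytest.raises(ValueError):
        pc.loglik_poisson([1], [0.0])


def test_loglik_airquality_closed_forms():
    # density exactly one per observation when var = 1/(2 pi)
    x = np.array([0.3, -0.1])
    assert pc.loglik_airquality(x, x, 1.0 / (2 * math.pi)) == pytest.approx(0.0)
    assert pc.loglik_airquality([1.0], [0.0], 1.0) == pytest.approx(-0.5 * (math.log(2 * math.pi) + 1))
    shifted = pc.loglik_airquality(x + 5.0, x + 5.0 - 0.2, 0.7)
    assert shifted == pytest.approx(pc.loglik_airquality(x, x - 0.2, 0.7))
    with pytest.raises(ValueError):
        pc.loglik_airquality(x, x, 0.0)


def test_t_process_approaches_normal_at_large_df():
    w = np.array([0.3, -0.8, 1.2])
    lp_t = process_logpdf(w, pc.ProcessSpec(family="student_t", df=1e6), 0.5)
    lp_n = process_logpdf(w, pc.ProcessSpec(family="normal"), 0.5)
    assert abs(lp_t - lp_n) < 1e-3


# ---------------------------------------------------------------------------
# prior and joint posterior against independent reimplementations


def scalar_log_prior(state, spec, source, target):
    """Block-wise scipy-based reimplementation of the joint log prior."""
    pr = spec.priors
    lp = 0.0
    for c in [*state.beta, *state.gamma, *state.delta, state.eta1]:
        lp += norm.logpdf(c, pr.coeff_mean, math.sqrt(pr.coeff_variance))
    for w, var in ((state.w1, state.var_w1), (state.w2, state.var_w2)):
        if spec.process.family == "normal":
            lp += norm.logpdf(w, 0, math.sqrt(var)).sum()
        else:
            lp += t_dist.logpdf(w, spec.process.df, scale=math.sqrt(var)).sum()
    for frame, e in ((source, state.e_source), (target, state.e_target)):
        off = frame.offset_prevalence
        v = np.exp(state.delta[0] + state.delta[1] * off / off.mean())
        lp += norm.logpdf(e, 0, np.sqrt(v)).sum()
    for var in (state.var_w1, state.var_w2, state.var_x):
        lp += gamma_dist.logpdf(1.0 / var, pr.precision_shape,
                                scale=1.0 / pr.precision_rate)
    return lp


@pytest.mark.parametrize("process", ["normal", "student_t"])
def test_log_prior_matches_blockwise_oracle(process):
    source, target, grid = toy_frames()
    state = toy_state()
    spec = pc.ModelSpec(process=pc.ProcessSpec(family=process, df=5.0))
    assert log_prior(state, spec, source, target) == pytest.approx(
        scalar_log_prior(state, spec, source, target), abs=1e-10)


def scalar_joint_log_posterior(state, source, target, grid, spec):
    """Fully independent scalar-loop reimplementation (the oracle)."""
    lp = scalar_log_prior(state, spec, source, target)

    def kw(d):
        if spec.kernel.family == "normal":
            return math.exp(-0.5 * (d / spec.kernel.scale) ** 2)
        if spec.kernel.family == "exponential":
            return math.exp(-d / spec.kernel.scale)
        k = spec.kernel.kernel_df
        return (1 + d**2 / (k * spec.kernel.scale**2)) ** (-(k + 2) / 2)

    def field(w, point):
        tot = 0.0
        for j in range(grid.n_points):
            d = math.hypot(point[0] - grid.points[j, 0],
                           point[1] - grid.points[j, 1]) / grid.spacing
            tot += kw(d) * w[j]
        return tot

    for i in range(source.n):
        s = source.centroids[i]
        xl = state.eta1 + field(state.w2, s)
        log_rho = state.beta[0] + state.beta[1] * xl + field(state.w1, s) + state.e_source[i]
        mu = source.offset_prevalence[i] * math.exp(log_rho)
        yi = source.count[i]
        lp += yi * math.log(mu) - mu - float(gammaln(yi + 1))
    for k in range(target.n):
        tpt = target.centroids[k]
        log_rho = (state.beta[0] + state.beta[1] * target.covariate[k]
                   + field(state.w1, tpt) + state.e_target[k])
        nu = math.exp(state.gamma[0] + state.gamma[1] * math.exp(log_rho))
        mu = target.offset_morbidity[k] * nu
        mk = target.count[k]
        lp += mk * math.log(mu) - mu - float(gammaln(mk + 1))
        mu_x = state.eta1 + field(state.w2, tpt)
        lp += (-0.5 * math.log(2 * math.pi * state.var_x)
               - (target.covariate[k] - mu_x) ** 2 / (2 * state.var_x))
    return lp


@pytest.mark.parametrize("variant", [1, 2, 3, 4])
def test_joint_log_posterior_matches_scalar_oracle_all_variants(variant):
    source, target, grid = toy_frames()
    state = toy_state()
    spec = pc.model_variant(variant)
    got = pc.joint_log_posterior(state, source, target, grid, spec)
    want = scalar_joint_log_posterior(state, source, target, grid, spec)
    assert got == pytest.approx(want, abs=1e-10)


def test_removing_hospitalisation_stream_changes_by_its_loglik(toy):
    source, target, grid = toy
    state = toy_state()
    spec = pc.ModelSpec()
    full = pc.joint_log_posterior(state, source, target, grid, spec)
    kt = kernel_matrix(target.centroids, grid, spec.kernel)
    log_rho_t = pc.log_relative_risk(state.beta, target.covariate,
                                     pc.convolve_field(state.w1, kt), state.e_target)
    log_nu = pc.hospitalisation_log_risk(state.gamma, np.exp(log_rho_t))
    ll_m = pc.loglik_poisson(target.count, target.offset_morbidity * np.exp(log_nu))
    # the remaining three components, reassembled without the M stream
    ks = kernel_matrix(source.centroids, grid, spec.kernel)
    xl = pc.latent_covariate(state.eta1, pc.convolve_field(state.w2, ks))
    log_rho_s = pc.log_relative_risk(state.beta, xl,
                                     pc.convolve_field(state.w1, ks), state.e_source)
    rest = (pc.loglik_poisson(source.count, source.offset_prevalence * np.exp(log_rho_s))
            + pc.loglik_airquality(target.covariate,
                                   state.eta1 + pc.convolve_field(state.w2, kt),
                                   state.var_x)
            + log_prior(state, spec, source, target))
    assert full == pytest.approx(rest + ll_m, abs=1e-9)


def test_shared_field_gives_equal_risk_at_coincident_centroids(toy):
    # a target centroid placed on a source centroid with equal covariate and
    # residual must carry the same relative risk: the frames share (beta, w1)
    source, target, grid = toy
    state = toy_state()
    spec = pc.ModelSpec()
    ks = kernel_matrix(source.centroids, grid, spec.kernel)
    z1_s = pc.convolve_field(state.w1, ks)
    xl = pc.latent_covariate(state.eta1, pc.convolve_field(state.w2, ks))
    lr_source = pc.log_relative_risk(state.beta, xl, z1_s, state.e_source)
    kt = kernel_matrix(source.centroids, grid, spec.kernel)  # coincident points
    lr_target = pc.log_relative_risk(state.beta, xl,
                                     pc.convolve_field(state.w1, kt), state.e_source)
    assert np.allclose(lr_source, lr_target)


def test_posterior_finite_and_prior_dominates_large_intercept(toy):
    source, target, grid = toy
    spec = pc.ModelSpec()
    state = toy_state()
    base = pc.joint_log_posterior(state, source, target, grid, spec)
    assert np.isfinite(base)
    lo = None
    for b1 in (-5.0, -20.0, -60.0):
        s = toy_state()
        s.beta = np.array([b1, s.beta[1]])
        val = pc.joint_log_posterior(s, source, target, grid, spec)
        if lo is not None:
            assert val < lo
        lo = val


def test_x_stream_decouples_when_beta2_and_w2_vanish(toy):
    # with beta2 = 0 and w2 = 0 the only x-dependence is the Gaussian stream:
    # permuting x changes the posterior by exactly the x-stream change
    source, target, grid = toy
    state = toy_state()
    state.beta = np.array([state.beta[0], 0.0])
    state.w2 = np.zeros(grid.n_points)
    spec = pc.ModelSpec()

    def x_loglik(tgt):
        kt = kernel_matrix(tgt.centroids, grid, spec.kernel)
        return pc.loglik_airquality(tgt.covariate, state.eta1 + pc.convolve_field(state.w2, kt),
                                    state.var_x)

    base = pc.joint_log_posterior(state, source, target, grid, spec)
    perm = np.array([2, 0, 1, 5, 3, 4])
    permuted = pc.AreaFrame(
        role="target", ids=target.ids, centroids=target.centroids,
        count=target.count, offset_prevalence=target.offset_prevalence,
        offset_morbidity=target.offset_morbidity,
        covariate=target.covariate[perm], adjacency=target.adjacency,
    )
    other = pc.joint_log_posterior(state, source, permuted, grid, spec)
    # conditional posterior of the prevalence block is unchanged: the shift
    # equals the x-stream log-likelihood difference alone
    assert other - base == pytest.approx(x_loglik(permuted) - x_loglik(target), abs=1e-9)


def test_param_state_validation():
    with pytest.raises(ValueError):
        pc.ParamState(beta=[0.0], gamma=[0, 0], delta=[0, 0], eta1=0.0,
                      w1=np.zeros(3), w2=np.zeros(3),
                      e_source=np.zeros(2), e_target=np.zeros(2))
    with pytest.raises(ValueError):
        pc.ParamState(beta=[0, 0], gamma=[0, 0], delta=[0, 0], eta1=0.0,
                      w1=np.zeros(3), w2=np.zeros(3),
                      e_source=np.zeros(2), e_target=np.zeros(2), var_w1=-1.0)
    state = toy_state()
    with pytest.raises(ValueError):
        state.validate(n_source=4, n_target=6, n_grid=5)
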