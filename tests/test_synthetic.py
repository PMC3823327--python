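"""Synthetic geography and dataset generator."""

import numpy as np
import pytest

import prevconv as pc
from prevconv.kernels import kernel_matrix
from prevconv.synthetic import generate_geography, generate_truth, simulate_observations


def test_default_geography_reproduces_study_dimensions():
    geo = generate_geography(seed=0)
    assert geo.source_centroids.shape == (189, 2)
    assert geo.target_centroids.shape == (562, 2)
    assert geo.grid.n_points == 84
    assert geo.grid.spacing == 2.0


def test_centroids_inside_extent_and_adjacency_valid():
    geo = generate_geography(n_source=40, n_target=90, region_extent=(10.0, 6.0),
                             seed=4)
    for pts in (geo.source_centroids, geo.target_centroids):
        assert np.all(pts[:, 0] >= 0) and np.all(pts[:, 0] <= 10.0)
        assert np.all(pts[:, 1] >= 0) and np.all(pts[:, 1] <= 6.0)
    for i, nb in enumerate(geo.adjacency):
        assert i not in nb
        for j in nb:
            assert i in geo.adjacency[j]


def test_geography_rejects_impossible_requests():
    with pytest.raises(ValueError):
        generate_geography(region_extent=(1.0, 1.0), grid_spacing=2.0)
    with pytest.raises(ValueError):
        generate_geography(n_source=0)


def test_uniform_option_spreads_points():
    # clustered centroids concentrate more than uniform ones
    clustered = generate_geography(n_target=300, seed=1, clustered=True)
    uniform = generate_geography(n_target=300, seed=1, clustered=False)
    d_c = np.sort(np.hypot(*(clustered.target_centroids[:, None]
                             - clustered.target_centroids[None]).transpose(2, 0, 1)), axis=1)[:, 1]
    d_u = np.sort(np.hypot(*(uniform.target_centroids[:, None]
                             - uniform.target_centroids[None]).transpose(2, 0, 1)), axis=1)[:, 1]
    assert np.median(d_c) < np.median(d_u)


def test_truth_fields_match_kernel_sum_oracle(small_dataset):
    _, _, grid, truth = small_dataset
    spec = pc.ModelSpec()
    ks = kernel_matrix(truth.geography.source_centroids, grid, spec.kernel)
    expected = np.array([
        sum(ks[i, j] * truth.state.w1[j] for j in range(grid.n_points))
        for i in range(ks.shape[0])
    ])
    assert np.allclose(truth.z1_source, expected)


def test_flat_truth_gives_constant_relative_risk():
    geo = generate_geography(n_source=15, n_target=30, region_extent=(4.0, 4.0),
                             seed=2, knn_k=4)
    cfg = pc.GeneratorConfig(n_source=15, n_target=30, region_extent=(4.0, 4.0),
                             var_w1=0.0, var_w2=0.0, beta=(-0.25, 0.0),
                             delta=(-np.inf, 0.0))
    truth = generate_truth(geo, pc.ModelSpec(), cfg, seed=0)
    assert np.allclose(truth.rho_source, np.exp(-0.25))
    assert np.allclose(truth.rho_target, np.exp(-0.25))
    assert np.all(truth.state.w1 == 0) and np.all(truth.state.e_source == 0)


def test_risk_equal_at_coincident_centroids():
    # shared field: same location, covariate and residual -> same rho
    geo = generate_geography(n_source=10, n_target=20, region_extent=(4.0, 4.0),
                             seed=3, knn_k=4, source_jitter_sd=0.0)
    cfg = pc.GeneratorConfig(delta=(-np.inf, 0.0), var_x=0.0)
    truth = generate_truth(geo, pc.ModelSpec(), cfg, seed=1)
    # each source centroid coincides with some target centroid (zero jitter)
    for i, s in enumerate(geo.source_centroids):
        matches = np.where((geo.target_centroids == s).all(axis=1))[0]
        if matches.size:
            assert truth.rho_source[i] == pytest.approx(truth.rho_target[matches[0]])


def test_observations_noise_free_limits():
    geo = generate_geography(n_source=12, n_target=25, region_extent=(4.0, 4.0),
                             seed=5, knn_k=4)
    cfg = pc.GeneratorConfig(var_x=0.0)
    truth = generate_truth(geo, pc.ModelSpec(), cfg, seed=2)
    _, target = simulate_observations(truth, seed=3)
    assert np.allclose(target.covariate, truth.x_mean)  # sigma_x = 0: exact


def test_observations_deterministic_and_poisson_mean():
    cfg = pc.GeneratorConfig(n_source=12, n_target=25, region_extent=(4.0, 4.0),
                             knn_k=4)
    geo = generate_geography(n_source=12, n_target=25, region_extent=(4.0, 4.0),
                             seed=6, knn_k=4)
    truth = generate_truth(geo, pc.ModelSpec(), cfg, seed=7)
    s1, t1 = simulate_observations(truth, seed=8)
    s2, t2 = simulate_observations(truth, seed=8)
    assert np.array_equal(s1.count, s2.count) and np.array_equal(t1.count, t2.count)
    # Monte-Carlo oracle: mean of y/E over replicates approaches rho
    reps = np.stack([
        simulate_observations(truth, seed=100 + r)[0].count / truth.offset_prev_source
        for r in range(1000)
    ])
    se = np.sqrt(truth.rho_source / truth.offset_prev_source / 1000)
    assert np.all(np.abs(reps.mean(axis=0) - truth.rho_source) < 3.5 * se + 1e-9)


def test_overdispersion_exceeds_poisson_prediction():
    # with residual variance on, var(log(y/E)) across areas exceeds the
    # pure-Poisson level implied by the expected counts
    cfg = pc.GeneratorConfig(n_source=200, n_target=30, region_extent=(6.0, 6.0),
                             var_w1=0.0, var_w2=0.0, beta=(0.0, 0.0),
                             delta=(-2.0, 0.0), knn_k=4)
    src, _, _, truth = pc.generate_dataset(cfg, seed=9)
    logratio = np.log(np.maximum(src.count, 0.5) / src.offset_prevalence)
    poisson_only = np.mean(1.0 / src.offset_prevalence)
    assert logratio.var() > 2 * poisson_only
    assert logratio.var() == pytest.approx(np.exp(-2.0) + poisson_only, rel=0.5)


def test_generate_dataset_reproducible():
    cfg = pc.GeneratorConfig(n_source=10, n_target=20, region_extent=(4.0, 4.0),
                             knn_k=4)
    a = pc.generate_dataset(cfg, seed=13)
    b = pc.generate_dataset(cfg, seed=13)
    assert np.array_equal(a[0].count, b[0].count)
    assert np.array_equal(a[1].covariate, b[1].covariate)
    assert np.allclose(a[3].rho_target, b[3].rho_target)


def test_morbidity_independent_of_x_given_latents():
    # x and M share only the latent surfaces: after conditioning on the true
    # rho and x-mean, their residual association vanishes
    cfg = pc.GeneratorConfig(n_source=10, n_target=400, region_extent=(12.0, 12.0),
                             n_parents=10)
    src, tgt, grid, truth = pc.generate_dataset(cfg, seed=21)
    m_resid = (tgt.count - tgt.offset_morbidity * truth.nu) / np.sqrt(tgt.offset_morbidity * truth.nu)
    x_resid = tgt.covariate - truth.x_mean
    r = np.corrcoef(m_resid, x_resid)[0, 1]
    assert abs(r) < 3.5 / np.sqrt(400)
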