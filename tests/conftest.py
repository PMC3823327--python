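"""Shared fixtures: a hand-built toy instance, a reduced-scale synthetic
study (the scale used for recovery/convergence checks), and a cached fit."""

from __future__ import annotations

import numpy as np
import pytest

import prevconv as pc

# reduced-scale study conditions: 60 service areas, 150 neighbourhoods,
# 5 x 5 grid at 2 km spacing, coefficients at the reported posterior means
REDUCED_CONFIG = pc.GeneratorConfig(
    n_source=60, n_target=150, region_extent=(8.0, 8.0), n_parents=8,
)


def toy_frames():
    """Deterministic N=4 / K=6 / J=3 instance with every data field set."""
    source = pc.AreaFrame(
        role="source",
        ids=np.array(["s1", "s2", "s3", "s4"]),
        centroids=np.array([[0.5, 0.5], [1.5, 0.6], [2.5, 1.4], [3.0, 0.2]]),
        count=np.array([12, 7, 15, 9]),
        offset_prevalence=np.array([10.0, 8.0, 14.0, 9.5]),
    )
    adjacency = [
        np.array([1, 2]), np.array([0, 2]), np.array([0, 1, 3]),
        np.array([2, 4]), np.array([3, 5]), np.array([4]),
    ]
    target = pc.AreaFrame(
        role="target",
        ids=np.array(["t1", "t2", "t3", "t4", "t5", "t6"]),
        centroids=np.array([
            [0.2, 0.8], [1.0, 1.2], [1.8, 0.4], [2.2, 1.0], [2.9, 0.7], [3.4, 1.3],
        ]),
        count=np.array([3, 0, 5, 2, 4, 1]),
        offset_prevalence=np.array([4.0, 3.5, 5.0, 4.2, 6.0, 3.8]),
        offset_morbidity=np.array([2.0, 1.8, 2.5, 2.1, 3.0, 1.9]),
        covariate=np.array([0.1, -0.3, 0.4, 0.0, -0.2, 0.3]),
        adjacency=adjacency,
    )
    grid = pc.Grid(points=np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]]), spacing=2.0)
    return source, target, grid


def toy_state(grid_n=3, n_source=4, n_target=6, seed=42):
    rng = np.random.default_rng(seed)
    return pc.ParamState(
        beta=np.array([-0.2, 0.3]), gamma=np.array([-1.5, 0.4]),
        delta=np.array([-2.0, 0.1]), eta1=0.15,
        w1=rng.normal(0, 0.5, grid_n), w2=rng.normal(0, 0.5, grid_n),
        e_source=rng.normal(0, 0.2, n_source), e_target=rng.normal(0, 0.2, n_target),
        var_w1=0.3, var_w2=0.4, var_x=0.05,
    )


@pytest.fixture(scope="session")
def toy():
    return toy_frames()


@pytest.fixture(scope="session")
def reduced_dataset():
    source, target, grid, truth = pc.generate_dataset(REDUCED_CONFIG, seed=0)
    return source, target, grid, truth


@pytest.fixture(scope="session")
def reduced_fit(reduced_dataset):
    """Two chains of 5,000 on the default reduced-scale fixture (cached)."""
    source, target, grid, _ = reduced_dataset
    config = pc.ChainConfig(n_chains=2, n_iter=5000, seed=0)
    return pc.run_mcmc(source, target, grid, pc.ModelSpec(), config)


@pytest.fixture(scope="session")
def study_dataset():
    """Generator defaults: the full 189/562/84 study-scale structure."""
    return pc.generate_dataset(pc.GeneratorConfig(), seed=0)


@pytest.fixture(scope="session")
def study_fit(study_dataset):
    """Two chains of 5,000 on the default study-scale fixture (cached)."""
    source, target, grid, _ = study_dataset
    config = pc.ChainConfig(n_chains=2, n_iter=5000, seed=0)
    return pc.run_mcmc(source, target, grid, pc.ModelSpec(), config)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = pc.GeneratorConfig(n_source=20, n_target=40, region_extent=(4.0, 4.0),
                             n_parents=4, knn_k=4)
    source, target, grid, truth = pc.generate_dataset(cfg, seed=3)
    return source, target, grid, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    source, target, grid, _ = small_dataset
    config = pc.ChainConfig(n_chains=2, n_iter=1200, seed=1)
    return pc.run_mcmc(source, target, grid, pc.ModelSpec(), config)
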