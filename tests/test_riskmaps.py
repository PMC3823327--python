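"""Exceedance probabilities, hotspot/cluster classification, crosstabs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prevconv as pc
from prevconv.riskmaps import (
    classify_clusters,
    classify_hotspots,
    cluster_centre_probability,
    crosstab_classifications,
    exceedance_probability,
    knn_adjacency,
    prevalence_percent,
)


def ring_adjacency(k):
    return [np.array([(i - 1) % k, (i + 1) % k]) for i in range(k)]


def test_exceedance_probability_counts_draws():
    draws = np.array([[0.9], [1.1], [1.2], [0.8]])
    assert exceedance_probability(draws)[0] == pytest.approx(0.5)
    assert exceedance_probability(np.full((10, 3), 2.0)) == pytest.approx([1, 1, 1])


def test_exceedance_matches_sorted_edf_oracle():
    rng = np.random.default_rng(0)
    draws = rng.lognormal(0, 0.5, size=(400, 7))
    p = exceedance_probability(draws)
    for k in range(7):
        srt = np.sort(draws[:, k])
        edf_at_one = np.searchsorted(srt, 1.0, side="right") / 400
        assert p[k] == pytest.approx(1 - edf_at_one)


def test_hotspot_threshold_strict():
    p = np.array([0.85, 0.8, 0.79])
    flags = classify_hotspots(p, 0.8)
    assert list(flags) == [True, False, False]
    with pytest.raises(ValueError):
        classify_hotspots(p, 1.2)
    with pytest.raises(ValueError):
        classify_hotspots(np.array([1.4]), 0.8)


def test_hotspots_nest_across_thresholds():
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 100)
    strict = classify_hotspots(p, 0.9)
    loose = classify_hotspots(p, 0.8)
    assert np.all(loose[strict])  # 0.9-hotspots are a subset of 0.8-hotspots


def test_cluster_centre_probability_single_draw_fraction():
    # one draw: centre exceeds, 2 of its 4 neighbours exceed -> 0.5
    rho = np.array([[1.2, 1.1, 0.9, 1.3, 0.7]])
    adjacency = [np.array([1, 2, 3, 4])] + [np.array([0])] * 4
    c = cluster_centre_probability(rho, adjacency)
    assert c[0] == pytest.approx(0.5)


def test_cluster_centre_probability_brute_force():
    rng = np.random.default_rng(2)
    draws = rng.lognormal(0, 0.4, size=(50, 8))
    adjacency = ring_adjacency(8)
    c = cluster_centre_probability(draws, adjacency)
    for k in range(8):
        acc = 0.0
        for r in range(50):
            jk = draws[r, k] > 1
            frac = np.mean([draws[r, l] > 1 for l in adjacency[k]])
            acc += jk * frac
        assert c[k] == pytest.approx(acc / 50)


def test_cluster_centre_degenerate_cases():
    draws = np.array([[0.5, 0.4], [0.9, 0.3]])
    adjacency = [np.array([1]), np.array([0])]
    assert np.all(cluster_centre_probability(draws, adjacency) == 0)
    draws = np.full((20, 3), 1.5)
    assert np.all(cluster_centre_probability(draws, ring_adjacency(3)) == 1.0)
    with pytest.raises(ValueError):
        cluster_centre_probability(draws, None)
    with pytest.warns(UserWarning):
        c = cluster_centre_probability(draws, [np.array([1]), np.array([0]), np.array([])])
        assert c[2] == 0.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_cluster_probability_bounded_by_exceedance(seed):
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(0, 0.6, size=(30, 6))
    c = cluster_centre_probability(draws, ring_adjacency(6))
    p = exceedance_probability(draws)
    assert np.all(c <= p + 1e-12)
    assert np.all((0 <= c) & (c <= 1))


def test_classifications_invariant_to_draw_order():
    rng = np.random.default_rng(3)
    draws = rng.lognormal(0, 0.5, size=(60, 5))
    perm = rng.permutation(60)
    adjacency = ring_adjacency(5)
    assert np.allclose(exceedance_probability(draws), exceedance_probability(draws[perm]))
    assert np.allclose(cluster_centre_probability(draws, adjacency),
                       cluster_centre_probability(draws[perm], adjacency))


def test_cluster_threshold_strict_and_monotone():
    c = np.array([0.3, 0.25, 0.2])
    assert list(classify_clusters(c, 0.25)) == [True, False, False]
    counts = [classify_clusters(c, t).sum() for t in (0.1, 0.25, 0.4)]
    assert counts == sorted(counts, reverse=True)


def test_crosstab_examples():
    a = np.array([True, True, False, False])
    assert np.array_equal(crosstab_classifications(a, a), [[2, 0], [0, 2]])
    assert np.array_equal(crosstab_classifications(a, ~a), [[0, 2], [2, 0]])
    nested = np.array([True, False, False, False])  # nested within a
    tab = crosstab_classifications(nested, a)
    assert tab[1, 0] == 0  # never flagged by the subset but not the superset
    assert tab.sum() == 4
    with pytest.raises(ValueError):
        crosstab_classifications(a, a[:3])


def test_prevalence_percent_baseline_and_scaling():
    draws = np.ones((200, 4))
    pct, summary = prevalence_percent(draws, 0.046)
    assert np.allclose(pct, 4.6)
    assert summary["mean"] == pytest.approx(4.6)
    rng = np.random.default_rng(4)
    draws = rng.lognormal(0, 0.3, size=(300, 50))
    pct1, s1 = prevalence_percent(draws, 0.02)
    pct2, s2 = prevalence_percent(draws, 0.04)
    assert np.allclose(pct2, 2 * pct1)
    for key in ("mean", "median", "p1", "p5", "p95", "p99"):
        assert s2[key] == pytest.approx(2 * s1[key])
    # quantile oracle by explicit sort
    means = np.sort(pct1)
    assert s1["p5"] == pytest.approx(np.percentile(means, 5))
    with pytest.raises(ValueError):
        prevalence_percent(draws, 1.5)


def test_knn_adjacency_symmetric_no_self_loops():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 10, size=(30, 2))
    adjacency = knn_adjacency(pts, k=5)
    for i, nb in enumerate(adjacency):
        assert i not in nb
        assert len(nb) >= 5
        for j in nb:
            assert i in adjacency[j]


def test_risk_summary_consistency(reduced_fit, reduced_dataset):
    _, target, _, _ = reduced_dataset
    summary = pc.risk_summary(reduced_fit, target, regional_rate=0.046)
    tab = summary.table
    assert len(tab) == target.n
    assert np.all(tab["cluster_prob"] <= tab["exceedance_prob"] + 1e-12)
    assert summary.n_hotspots == int((tab["exceedance_prob"] > 0.8).sum())
    assert summary.n_cluster_centres == int((tab["cluster_prob"] > 0.25).sum())
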