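"""Posterior risk classification for target areas.

From retained draws of the neighbourhood relative prevalence rho_k the module
computes exceedance probabilities p_k = Pr(rho_k > 1 | y, M, x), hotspot
flags (p_k above a threshold, conventionally 0.8 or 0.9), cluster-centre
probabilities C_k = E[ J_k * (1/L_k) sum_{l in A_k} J_l ] with
J_k = I(rho_k > 1) and A_k the adjacency set of area k, cluster flags
(C_k > 0.25 by default — attainable once the area and at least one
neighbour jointly exceed), cross-model co-location tables, and conversion of
relative risks to prevalence percentages via the region-wide rate.

Thresholds are applied strictly (flag iff probability > threshold); the
boundary case is measure-zero in practice but the convention matters for
reproducibility.  C_k <= p_k always, since the product of indicators is at
most the first indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskSummary",
    "exceedance_probability",
    "classify_hotspots",
    "cluster_centre_probability",
    "classify_clusters",
    "crosstab_classifications",
    "prevalence_percent",
    "risk_summary",
    "knn_adjacency",
]


def _as_draws(rho_draws) -> np.ndarray:
    arr = np.asarray(rho_draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("rho draws must be a nonempty (draws, K) array")
    return arr


def exceedance_probability(rho_draws) -> np.ndarray:
    """p_k = fraction of draws with rho_k > 1."""
    return (_as_draws(rho_draws) > 1.0).mean(axis=0)


def classify_hotspots(p, threshold: float = 0.8) -> np.ndarray:
    """Strict exceedance-probability threshold: flag iff p > threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return p > threshold


def cluster_centre_probability(rho_draws, adjacency) -> np.ndarray:
    """C_k = posterior mean of J_k x (fraction of neighbours with J_l = 1).

    Isolated areas (empty adjacency set) get C_k = 0 with a warning.
    """
    draws = _as_draws(rho_draws)
    k_areas = draws.shape[1]
    if adjacency is None or len(adjacency) != k_areas:
        raise ValueError("adjacency must supply one neighbour list per area")
    exceed = draws > 1.0
    out = np.zeros(k_areas)
    isolated = [k for k in range(k_areas) if len(adjacency[k]) == 0]
    if isolated:
        warnings.warn(f"{len(isolated)} isolated area(s) assigned cluster probability 0")
    for k in range(k_areas):
        nb = np.asarray(adjacency[k], dtype=np.int64)
        if nb.size == 0:
            continue
        out[k] = float(np.mean(exceed[:, k] * exceed[:, nb].mean(axis=1)))
    return out


def classify_clusters(c, threshold: float = 0.25) -> np.ndarray:
    """Strict cluster-probability threshold: flag iff C > threshold."""
    return classify_hotspots(c, threshold)


def crosstab_classifications(flags_a, flags_b) -> np.ndarray:
    """2x2 co-location table: rows = a (no, yes), columns = b (no, yes)."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must have equal length")
    return np.array([
        [int(np.sum(~a & ~b)), int(np.sum(~a & b))],
        [int(np.sum(a & ~b)), int(np.sum(a & b))],
    ])


def prevalence_percent(rho_draws, regional_rate: float) -> tuple[np.ndarray, dict[str, float]]:
    """Per-area posterior-mean prevalence percentages and their distribution.

    Per draw, prevalence_k = 100 x regional_rate x rho_k; summaries (mean,
    median, skewness, percentiles 1/5/95/99) are taken over the posterior
    means across areas.
    """
    if not (0.0 < regional_rate < 1.0):
        raise ValueError("regional_rate must lie in (0, 1)")
    draws = _as_draws(rho_draws)
    per_area = 100.0 * regional_rate * draws.mean(axis=0)
    summary = {
        "mean": float(per_area.mean()),
        "median": float(np.median(per_area)),
        "skewness": float(stats.skew(per_area)),
        "p1": float(np.percentile(per_area, 1)),
        "p5": float(np.percentile(per_area, 5)),
        "p95": float(np.percentile(per_area, 95)),
        "p99": float(np.percentile(per_area, 99)),
    }
    return per_area, summary


@dataclass(frozen=True)
class RiskSummary:
    """Per-area classification table plus the thresholds that produced it."""

    table: pd.DataFrame
    hotspot_threshold: float
    cluster_threshold: float
    regional_rate: float

    @property
    def n_hotspots(self) -> int:
        return int(self.table["hotspot"].sum())

    @property
    def n_cluster_centres(self) -> int:
        return int(self.table["cluster_centre"].sum())


def risk_summary(draws, target, regional_rate: float,
                 hotspot_threshold: float = 0.8,
                 cluster_threshold: float = 0.25) -> RiskSummary:
    """Full classification of the target frame from posterior draws."""
    rho = draws.stacked("rho_target") if hasattr(draws, "stacked") else _as_draws(draws)
    p = exceedance_probability(rho)
    if target.adjacency is None:
        raise ValueError("target frame has no adjacency; cluster probabilities need one")
    c = cluster_centre_probability(rho, target.adjacency)
    pct, _ = prevalence_percent(rho, regional_rate)
    table = pd.DataFrame({
        "area_id": target.ids,
        "exceedance_prob": p,
        "cluster_prob": c,
        "hotspot": classify_hotspots(p, hotspot_threshold),
        "cluster_centre": classify_clusters(c, cluster_threshold),
        "prevalence_percent": pct,
    })
    return RiskSummary(table=table, hotspot_threshold=hotspot_threshold,
                       cluster_threshold=cluster_threshold, regional_rate=regional_rate)


def knn_adjacency(centroids, k: int = 5) -> list[np.ndarray]:
    """Symmetric k-nearest-neighbour adjacency on planar centroids.

    Each area's k nearest neighbours are linked, then the relation is
    symmetrised (union), so L_k >= k.
    """
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if n <= k:
        raise ValueError("need more areas than neighbours")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = np.argsort(d2, axis=1)[:, :k]
    sets: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in nearest[i]:
            sets[i].add(int(j))
            sets[int(j)].add(i)
    return [np.array(sorted(s), dtype=np.int64) for s in sets]
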