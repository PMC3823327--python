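"""Areal data containers: one spatial framework (source or target).

Source areas are the frame on which prevalence counts are observed (e.g., GP
practice service areas, counts y_i with expected prevalence E_i).  Target
areas are the frame to which prevalence is interpolated (e.g., neighbourhoods
/ LSOAs) carrying hospitalisation counts M_k with expected counts G_k, an
expected-prevalence offset E_k, a log air-quality covariate x_k, and an
adjacency structure used for cluster-centre probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AreaFrame"]


@dataclass
class AreaFrame:
    """One spatial framework with counts, offsets and optional extras.

    Parameters
    ----------
    role
        ``"source"`` or ``"target"``.
    ids
        Unique area identifiers (order preserved everywhere downstream).
    centroids
        (P, 2) planar coordinates in km (population-weighted centroids).
    count
        Observed counts: prevalence y_i on the source frame, hospitalisations
        M_k on the target frame.
    offset_prevalence
        Expected prevalence counts (population x region-wide rate), E_i / E_k.
    offset_morbidity
        Expected hospitalisation counts G_k (target frame only).
    covariate
        Log air-quality index x_k (target frame only).
    adjacency
        Per-area neighbour index lists A_k (target frame only); symmetric,
        irreflexive, indices into this frame's row order.
    """

    role: str
    ids: np.ndarray
    centroids: np.ndarray
    count: np.ndarray
    offset_prevalence: np.ndarray
    offset_morbidity: np.ndarray | None = None
    covariate: np.ndarray | None = None
    adjacency: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("source", "target"):
            raise ValueError("role must be 'source' or 'target'")
        self.ids = np.asarray(self.ids)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.count = np.asarray(self.count)
        self.offset_prevalence = np.asarray(self.offset_prevalence, dtype=float)
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            dup = self.ids[np.argmax(np.unique(self.ids, return_counts=True)[1] > 1)]
            raise ValueError(f"duplicate area_id in {self.role} frame")
        if self.centroids.shape != (n, 2):
            raise ValueError("centroids must be (n, 2)")
        if self.count.shape != (n,) or np.any(self.count < 0):
            raise ValueError("counts must be nonnegative, one per area")
        if np.any(~(np.asarray(self.count) == np.floor(self.count))):
            raise ValueError("counts must be integers")
        self.count = self.count.astype(np.int64)
        if self.offset_prevalence.shape != (n,) or np.any(self.offset_prevalence <= 0):
            bad = int(np.argmax(self.offset_prevalence <= 0))
            raise ValueError(f"offset_prevalence must be positive (row {bad}, id {self.ids[bad]!r})")
        if self.offset_morbidity is not None:
            self.offset_morbidity = np.asarray(self.offset_morbidity, dtype=float)
            if self.offset_morbidity.shape != (n,) or np.any(self.offset_morbidity <= 0):
                raise ValueError("offset_morbidity must be positive, one per area")
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if self.role != "target":
                raise ValueError("covariate is only carried on the target frame")
            if self.covariate.shape != (n,) or not np.all(np.isfinite(self.covariate)):
                raise ValueError("covariate must be finite, one per area")
        if self.adjacency is not None:
            if len(self.adjacency) != n:
                raise ValueError("adjacency must have one neighbour list per area")
            self.adjacency = [np.asarray(a, dtype=np.int64) for a in self.adjacency]
            for k, nb in enumerate(self.adjacency):
                if np.any(nb == k):
                    raise ValueError(f"adjacency contains a self-loop at area {k}")
                for l in nb:
                    if k not in self.adjacency[l]:
                        raise ValueError(f"adjacency is not symmetric ({k} -> {l})")

    @property
    def n(self) -> int:
        return len(self.ids)
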