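"""Smoothing kernels and kernel-weight matrices for discrete process convolution.

A latent spatial field is represented as a kernel-weighted sum of random
effects sited at a sparse regular grid: z(s) = sum_j k(|s - u_j|) w_j.  This
module supplies the kernel families (bivariate normal, exponential and
Student-t, all isotropic and standardised so that k(0) = 1), the grid
container, and the dense area-by-grid weight matrices that link area
centroids to grid points.

Distances are standardised by the grid spacing before kernel evaluation, so
a "standard" kernel (scale 1) has scale equal to one grid interval.
Normalising constants are deliberately dropped: the kernel is standardised
and the overall field amplitude is carried by the grid-process variance
(estimating both would leave them confounded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "Grid",
    "kernel_weight",
    "standardised_distances",
    "kernel_matrix",
]

_FAMILIES = ("normal", "exponential", "student_t")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and scale, in grid-spacing units.

    ``scale`` is alpha for the normal kernel and eta for the exponential;
    ``kernel_df`` is the Student-t shape and is ignored by the other
    families.
    """

    family: str = "normal"
    scale: float = 1.0
    kernel_df: float = 5.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}")
        if not (self.scale > 0):
            raise ValueError("kernel scale must be positive")
        if not (self.kernel_df > 0):
            raise ValueError("kernel_df must be positive")


@dataclass(frozen=True)
class Grid:
    """Discrete grid of J points supporting the convolution processes."""

    points: np.ndarray  # (J, 2) planar coordinates, km
    spacing: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("grid points must be a (J, 2) array with J >= 1")
        if not np.all(np.isfinite(pts)):
            raise ValueError("grid points must be finite")
        if not (self.spacing > 0):
            raise ValueError("grid spacing must be positive")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("grid points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @classmethod
    def regular(cls, bounds: tuple[float, float, float, float], spacing: float = 2.0) -> "Grid":
        """Regular lattice covering ``bounds`` = (xmin, ymin, xmax, ymax).

        Lattice points run from each lower bound in steps of ``spacing`` up
        to and including the first point at or beyond the upper bound, so the
        returned grid always covers the box.
        """
        xmin, ymin, xmax, ymax = bounds
        if not (xmax >= xmin and ymax >= ymin):
            raise ValueError("degenerate bounds")
        nx = int(np.ceil((xmax - xmin) / spacing)) + 1
        ny = int(np.ceil((ymax - ymin) / spacing)) + 1
        xs = xmin + spacing * np.arange(nx)
        ys = ymin + spacing * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return cls(points=np.column_stack([gx.ravel(), gy.ravel()]), spacing=spacing)

    @classmethod
    def from_table(cls, df, spacing: float) -> "Grid":
        """Grid from a table with columns grid_id, easting, northing."""
        pts = np.column_stack([np.asarray(df["easting"], float), np.asarray(df["northing"], float)])
        return cls(points=pts, spacing=spacing)


def kernel_weight(d, spec: KernelSpec):
    """Evaluate the standardised kernel at nonnegative standardised distance d.

    Returns a weight in (0, 1], equal to 1 at d = 0 and strictly decreasing
    in d.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if spec.family == "normal":
        w = np.exp(-0.5 * (d / spec.scale) ** 2)
    elif spec.family == "exponential":
        w = np.exp(-d / spec.scale)
    else:  # student_t
        k = spec.kernel_df
        w = (1.0 + d**2 / (k * spec.scale**2)) ** (-(k + 2.0) / 2.0)
    if w.ndim == 0:
        return float(w)
    return w


def standardised_distances(points, grid: Grid) -> np.ndarray:
    """P x J matrix of Euclidean distances divided by the grid spacing."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a nonempty (P, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    diff = pts[:, None, :] - grid.points[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)) / grid.spacing


def kernel_matrix(points, grid: Grid, spec: KernelSpec) -> np.ndarray:
    """Dense P x J matrix of kernel weights linking points to grid sites."""
    return np.asarray(kernel_weight(standardised_distances(points, grid), spec))
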