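"""Parcellation geometry on the unit sphere.

A parcellated cortical analysis only needs, per region, a label and a notion of
inter-region distance.  Here regions are represented by centroids on the unit
sphere (a stand-in for an inflated cortical surface) and distance is the
great-circle distance between centroids, which feeds both the synthetic
spatially-clustered effects and the spatial-autocorrelation null models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ParcellationGeometry:
    """Region labels, unit-sphere centroids and a pairwise distance matrix.

    Attributes
    ----------
    region_ids : list of str
        Region labels; row order of ``coords`` and ``dist`` follows this order.
    coords : ndarray of shape (n_regions, 3)
        Centroid coordinates on the unit sphere.
    dist : ndarray of shape (n_regions, n_regions)
        Symmetric non-negative distance matrix with a zero diagonal.
    """

    region_ids: list[str]
    coords: np.ndarray
    dist: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        coords = np.asarray(self.coords, dtype=float)
        dist = np.asarray(self.dist, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(f"coords must have shape ({n}, 3), got {coords.shape}")
        if dist.shape != (n, n):
            raise ValueError(f"dist must have shape ({n}, {n}), got {dist.shape}")
        if not np.allclose(dist, dist.T):
            raise ValueError("dist must be symmetric")
        if not np.allclose(np.diag(dist), 0.0):
            raise ValueError("dist must have a zero diagonal")
        off = dist[~np.eye(n, dtype=bool)]
        if off.size and off.min() <= 0:
            raise ValueError("off-diagonal distances must be strictly positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "dist", dist)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def great_circle_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances between unit vectors (radians)."""
    coords = np.asarray(coords, dtype=float)
    gram = np.clip(coords @ coords.T, -1.0, 1.0)
    dist = np.arccos(gram)
    np.fill_diagonal(dist, 0.0)
    return 0.5 * (dist + dist.T)


def make_geometry(n_regions: int, seed: int = 0) -> ParcellationGeometry:
    """Quasi-uniform region centroids on the unit sphere (Fibonacci lattice).

    The lattice is given a random rotation drawn from ``seed`` so that
    different seeds yield different (but equally uniform) geometries.

    Parameters
    ----------
    n_regions : int
        Number of regions; must be >= 1.
    seed : int
        Seed for the random rotation.
    """
    if int(n_regions) < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    n_regions = int(n_regions)
    i = np.arange(n_regions, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_regions
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:  # keep a proper rotation
        q[:, 0] = -q[:, 0]
    coords = coords @ q.T
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)

    region_ids = [f"R{k:04d}" for k in range(n_regions)]
    return ParcellationGeometry(region_ids, coords, great_circle_distances(coords))
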