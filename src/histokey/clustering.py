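"""K-means "features" over patch latent vectors.

Each cluster of latent vectors is a candidate image feature; the number of
clusters defaults to the number of distinct training slides (38 in the
reference cohort).  Any patch is assigned to its nearest centroid by
Euclidean distance; the one-hot indicator u over clusters has a single 1
at the argmin, with exact-distance ties broken toward the lowest cluster
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = ["CentroidSet", "Assignment", "fit_kmeans", "assign_latents", "assign_patch"]


@dataclass
class CentroidSet:
    """Fitted cluster centroids plus fit metadata."""

    centroids: np.ndarray  # (k, latent_dim)
    seed: Optional[int] = None
    inertia: Optional[float] = None
    n_iter: Optional[int] = None

    @property
    def k(self) -> int:
        return int(self.centroids.shape[0])

    @property
    def latent_dim(self) -> int:
        return int(self.centroids.shape[1])


@dataclass
class Assignment:
    """Nearest-centroid assignment of one patch.

    ``distances`` holds the Euclidean distance to each of the k centroids;
    ``indicator`` (u) is 1 at the argmin and 0 elsewhere.
    """

    cluster: int
    distances: np.ndarray
    slide_id: Optional[str] = None
    origin: Optional[tuple[int, int]] = None
    indicator: np.ndarray = field(init=False)

    def __post_init__(self):
        u = np.zeros(len(self.distances), dtype=np.int8)
        u[self.cluster] = 1
        self.indicator = u


def fit_kmeans(latents: np.ndarray, k: int, seed: Optional[int] = None) -> CentroidSet:
    """Fit k-means (k-means++ init, 10 restarts, keep the lowest inertia)."""
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2:
        raise ValueError(f"expected (n, latent_dim) matrix, got shape {latents.shape}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if latents.shape[0] < k:
        raise ValueError(f"need at least k={k} latent vectors, got {latents.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    km.fit(latents)
    return CentroidSet(
        centroids=km.cluster_centers_.copy(),
        seed=seed,
        inertia=float(km.inertia_),
        n_iter=int(km.n_iter_),
    )


def assign_latents(latents: np.ndarray, centroids: CentroidSet) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid assignment for a latent matrix.

    Returns ``(labels, distances)`` where ``labels[i]`` is the index of the
    closest centroid (ties -> lowest index) and ``distances`` is the full
    (n, k) Euclidean distance matrix.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    if latents.shape[1] != centroids.latent_dim:
        raise ValueError(
            f"latent dimension {latents.shape[1]} does not match centroid "
            f"dimension {centroids.latent_dim}"
        )
    distances = cdist(latents, centroids.centroids, metric="euclidean")
    labels = np.argmin(distances, axis=1)  # argmin returns the first minimum
    return labels, distances


def assign_patch(
    latent: np.ndarray,
    centroids: CentroidSet,
    slide_id: Optional[str] = None,
    origin: Optional[tuple[int, int]] = None,
) -> Assignment:
    """Assign a single patch latent to its nearest cluster."""
    labels, distances = assign_latents(np.asarray(latent)[None], centroids)
    return Assignment(
        cluster=int(labels[0]),
        distances=distances[0],
        slide_id=slide_id,
        origin=origin,
    )
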