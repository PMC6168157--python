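"""3D niche statistics for HSC centroids from whole-mount imaging.

Within each imaged field of view, nearest-neighbour distances between
HSC centroids are computed in 3D, cells closer than an adjacency radius
(default 19 μm: largest HSC radius 7 + 7 + smallest intervening
bone-marrow cell radius 5) are linked, and the clustered fraction is
the share of cells in connected components of two or more.  Distance
histograms use half-open 20 μm bins.  Distances are never computed
across fields of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "CentroidSet",
    "NicheClusterer",
    "nn_distances",
    "clusters",
    "distance_histogram",
]


@dataclass(frozen=True)
class CentroidSet:
    """Labelled 3D HSC positions (μm) of one field of view."""

    points: np.ndarray  # (n, 3)
    group: str = ""
    field_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if pts.shape[0] < 1:
            raise ValueError("need at least one point per field")
        if not np.isfinite(pts).all():
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def nn_distances(cs: CentroidSet) -> np.ndarray:
    """Euclidean 3D distance from each centroid to its closest neighbour
    within the same field; a singleton field raises."""
    if cs.n < 2:
        raise ValueError(f"field {cs.field_id!r}: singleton field has no neighbour")
    tree = cKDTree(cs.points)
    d, _ = tree.query(cs.points, k=2)
    return d[:, 1]


class NicheClusterer(BaseEstimator, ClusterMixin):
    """Adjacency clustering of 3D centroids.

    Parameters
    ----------
    adjacency : float
        Strict centroid-to-centroid distance (μm) below which two cells
        are adjacent.
    bin_width : float
        Width of the nearest-neighbour distance histogram bins (μm).

    Attributes
    ----------
    labels_ : ndarray
        Connected-component label per point.
    clustered_fraction_ : float
        Fraction of points in components of size >= 2.
    nn_distances_ : ndarray
        Per-point nearest-neighbour distance (NaN for singleton fields).
    """

    def __init__(self, adjacency: float = 19.0, bin_width: float = 20.0):
        self.adjacency = adjacency
        self.bin_width = bin_width

    def fit(self, X, y=None):
        cs = X if isinstance(X, CentroidSet) else CentroidSet(points=np.asarray(X))
        pts = cs.points
        n = len(pts)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(self.adjacency, output_type="ndarray")
        # strict inequality: drop pairs at exactly the threshold
        if len(pairs):
            d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
            pairs = pairs[d < self.adjacency]
        if len(pairs):
            i = np.concatenate([pairs[:, 0], pairs[:, 1]])
            j = np.concatenate([pairs[:, 1], pairs[:, 0]])
            adj = csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        else:
            adj = csr_matrix((n, n))
        n_comp, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        self.labels_ = labels
        self.component_sizes_ = sizes
        self.clustered_fraction_ = float((sizes[labels] >= 2).mean())
        self.nn_distances_ = nn_distances(cs) if n >= 2 else np.full(n, np.nan)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def histogram(self) -> pd.DataFrame:
        """Fraction of points per nearest-neighbour distance bin
        ([0, w), [w, 2w), ...); fractions sum to 1 over points with a
        neighbour."""
        d = self.nn_distances_[np.isfinite(self.nn_distances_)]
        if len(d) == 0:
            return pd.DataFrame(columns=["bin_low", "bin_high", "fraction"])
        n_bins = int(np.floor(d.max() / self.bin_width)) + 1
        edges = np.arange(n_bins + 1) * self.bin_width
        counts, _ = np.histogram(d, bins=edges)
        return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                             "fraction": counts / len(d)})


def clusters(cs: CentroidSet, adjacency: float = 19.0) -> dict:
    """Connected components under the strict adjacency rule."""
    m = NicheClusterer(adjacency=adjacency).fit(cs)
    comp_sizes = m.component_sizes_
    return {"labels": m.labels_, "component_sizes": comp_sizes,
            "n_clusters": int((comp_sizes >= 2).sum()),
            "clustered_fraction": m.clustered_fraction_}


def distance_histogram(cs: CentroidSet, bin_width: float = 20.0) -> pd.DataFrame:
    return NicheClusterer(bin_width=bin_width).fit(cs).histogram()


def clustered_fraction_from_nn(nn: np.ndarray, adjacency: float = 19.0) -> float:
    """Lower-level entry for datasets shipping only nearest-neighbour
    distances (no coordinates): fraction of cells whose nearest
    neighbour lies strictly within the adjacency radius."""
    nn = np.asarray(nn, dtype=float)
    return float((nn < adjacency).mean())
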