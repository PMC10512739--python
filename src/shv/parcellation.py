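"""Data-driven pre-segmentation of the brain into voxel clusters.

Voxels with similar response profiles that are spatially close are grouped
into small clusters by normalized-cut spectral clustering of an affinity
graph.  The affinity between voxels v1 and v2 is

    A(v1, v2) = |corr(X[:, v1], X[:, v2])| * exp(-dist(v1, v2)^2 / sigma_d^2)

where ``corr`` is the Pearson correlation of the two voxel columns of a
(scans x voxels) data matrix, ``dist`` the Euclidean distance of the voxel
coordinates in voxel units, and ``sigma_d`` a connection radius attenuating
far-away voxels.  A single segmentation is shared by all subjects, so the
affinity is computed on the combined (row-stacked, per-subject standardized)
data of the group.

The resulting :class:`Parcellation` assigns every in-mask voxel to exactly
one of ``n_clusters`` clusters; cluster averages of voxel features are the
low-dimensional predictors of the group-sparse decoding model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .mask import VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityGraph",
    "Parcellation",
    "compute_affinity",
    "ncut_parcellate",
    "combined_group_data",
]


@dataclass(frozen=True)
class AffinityGraph:
    """Sparse symmetric voxel affinity matrix with unit diagonal.

    ``weights[v1, v2]`` is the correlation-times-distance-kernel affinity for
    voxel pairs within ``support_radius`` (voxel units) and 0 beyond; the
    diagonal is fixed at 1 (a voxel is perfectly affine to itself).
    """

    weights: sp.csr_matrix
    sigma_d: float
    support_radius: float

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError("affinity matrix must be square")
        if self.sigma_d <= 0 or self.support_radius <= 0:
            raise ValueError("sigma_d and support_radius must be positive")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class Parcellation:
    """Assignment of every in-mask voxel to one of ``n_clusters`` clusters.

    ``labels[v]`` is the cluster id (0-based) of in-mask voxel ``v`` in mask
    linear order.  Every cluster is non-empty; clusters partition the mask.
    """

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.intp)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1D array over in-mask voxels")
        if labels.size == 0:
            raise ValueError("parcellation over an empty mask")
        if labels.min() < 0 or labels.max() >= self.n_clusters:
            raise ValueError("cluster ids must lie in [0, n_clusters)")
        present = np.unique(labels)
        if present.size != self.n_clusters:
            raise ValueError("every cluster id in [0, n_clusters) must be non-empty")
        object.__setattr__(self, "labels", labels)

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    def cluster_members(self, j: int) -> np.ndarray:
        """Voxel linear indices of cluster ``j`` (the set g_j)."""
        return np.flatnonzero(self.labels == j)

    def members(self) -> list[np.ndarray]:
        order = np.argsort(self.labels, kind="stable")
        bounds = np.searchsorted(self.labels[order], np.arange(self.n_clusters + 1))
        return [order[bounds[j]:bounds[j + 1]] for j in range(self.n_clusters)]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def _standardize_columns(data: np.ndarray) -> np.ndarray:
    """Z-score columns; constant columns become all-zero (warned)."""
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    const = sd == 0
    if const.any():
        logger.warning(
            "%d constant column(s): correlations involving them set to 0", int(const.sum())
        )
    sd = np.where(const, 1.0, sd)
    out = (data - mean) / sd
    out[:, const] = 0.0
    return out


def compute_affinity(
    data: np.ndarray,
    mask: VoxelMask,
    sigma_d: float = 3.0,
    support_radius: float | None = None,
) -> AffinityGraph:
    """Build the voxel affinity graph from a (scans x voxels) data matrix.

    Parameters
    ----------
    data : (N_t, N_V) array
        Signal matrix whose columns follow ``mask`` linear order; raw time
        series, trial features, or their combination (see
        :func:`combined_group_data`).
    mask : VoxelMask
        Defines voxel coordinates, hence pairwise distances.
    sigma_d : float
        Connection radius of the Gaussian distance kernel, voxel units.
    support_radius : float, optional
        Pairs farther apart than this get affinity exactly 0.  Default
        ``3 * sigma_d`` (the kernel is below e^-9 there), keeping the graph
        sparse.

    Returns
    -------
    AffinityGraph
        Symmetric, entries in [0, 1], unit diagonal.
    """
    data = np.asarray(data, dtype=float)
    if mask.n_voxels == 0:
        raise ValueError("empty mask: no voxels to connect")
    if data.ndim != 2 or data.shape[1] != mask.n_voxels:
        raise ValueError(
            f"data must have one column per in-mask voxel ({mask.n_voxels}), got {data.shape}"
        )
    if sigma_d <= 0:
        raise ValueError("sigma_d must be positive")
    if support_radius is None:
        support_radius = 3.0 * sigma_d

    z = _standardize_columns(data) / np.sqrt(data.shape[0])  # corr = z_i . z_j
    coords = mask.coords.astype(float)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=support_radius, output_type="ndarray")

    n = mask.n_voxels
    if pairs.size:
        v1, v2 = pairs[:, 0], pairs[:, 1]
        corr = np.abs(np.einsum("ij,ij->i", z[:, v1].T, z[:, v2].T))
        # guard fp drift: |corr| <= 1
        np.clip(corr, 0.0, 1.0, out=corr)
        d2 = np.sum((coords[v1] - coords[v2]) ** 2, axis=1)
        vals = corr * np.exp(-d2 / sigma_d**2)
        rows = np.concatenate([v1, v2, np.arange(n)])
        cols = np.concatenate([v2, v1, np.arange(n)])
        data_ = np.concatenate([vals, vals, np.ones(n)])
    else:
        rows = cols = np.arange(n)
        data_ = np.ones(n)
    weights = sp.csr_matrix((data_, (rows, cols)), shape=(n, n))
    return AffinityGraph(weights=weights, sigma_d=float(sigma_d), support_radius=float(support_radius))


def _fiedler_split(weights: sp.csr_matrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-way split of a voxel subset by the sign of its Fiedler vector."""
    sub = weights[np.ix_(idx, idx)].toarray()
    deg = sub.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    lap = np.eye(len(idx)) - dinv[:, None] * sub * dinv[None, :]
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    left = fiedler <= np.median(fiedler)
    if left.all() or not left.any():  # degenerate: split in half deterministically
        left = np.zeros(len(idx), dtype=bool)
        left[: len(idx) // 2] = True
    return idx[left], idx[~left]


def ncut_parcellate(affinity: AffinityGraph, n_clusters: int, seed: int = 0) -> Parcellation:
    """Partition voxels into ``n_clusters`` clusters by normalized cuts.

    Realized as spectral clustering: k-means (fixed seed) on the leading
    eigenvectors of the symmetric normalized Laplacian of the affinity
    graph.  Deterministic given ``seed``.  Empty clusters -- possible when
    k-means collapses centroids -- are repaired by repeatedly splitting the
    largest cluster at its Fiedler vector.

    Raises
    ------
    ValueError
        If the graph has more connected components than ``n_clusters``
        (increase ``support_radius`` so distant voxels connect).
    """
    n = affinity.n_voxels
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    n_comp, _ = connected_components(affinity.weights, directed=False)
    if n_comp > n_clusters:
        raise ValueError(
            f"affinity graph has {n_comp} connected components > n_clusters={n_clusters}; "
            "increase support_radius to connect distant voxels"
        )
    if n_clusters == n:
        return Parcellation(labels=np.arange(n), n_clusters=n)

    w = affinity.weights.toarray()
    deg = w.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    # symmetric normalized Laplacian; dense eigh keeps the result deterministic
    lap = np.eye(n) - dinv[:, None] * w * dinv[None, :]
    _, vecs = np.linalg.eigh(lap)
    emb = vecs[:, :n_clusters]
    # row-normalize the spectral embedding (Ng-Jordan-Weiss)
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    labels = km.fit_predict(emb)

    # repair empty clusters by splitting the largest at its weakest cut
    present = np.unique(labels)
    missing = sorted(set(range(n_clusters)) - set(present.tolist()))
    while missing:
        target = missing.pop(0)
        sizes = np.bincount(labels, minlength=n_clusters)
        biggest = int(np.argmax(sizes))
        idx = np.flatnonzero(labels == biggest)
        _, right = _fiedler_split(affinity.weights, idx)
        labels[right] = target

    # canonical relabel: clusters numbered by first-occurrence order
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels], dtype=np.intp)
    return Parcellation(labels=labels, n_clusters=n_clusters)


def combined_group_data(datasets: list[np.ndarray]) -> np.ndarray:
    """Row-stack per-subject data for a single group-level segmentation.

    Each subject's matrix is column z-scored first so that subjects with
    different signal scales contribute equally to the pooled correlations.
    """
    if not datasets:
        raise ValueError("no datasets given")
    n_cols = {np.asarray(d).shape[1] for d in datasets}
    if len(n_cols) != 1:
        raise ValueError(f"all datasets must share the voxel dimension, got columns {sorted(n_cols)}")
    return np.vstack([_standardize_columns(np.asarray(d, dtype=float)) for d in datasets])
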