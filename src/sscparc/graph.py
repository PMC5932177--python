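"""Functional similarity graph and spatial-neighbor matrix.

The graph G = (V, E) has one node per ROI voxel and edge weights
f_uv = r_uv + 1, where r_uv is the Pearson correlation of the two voxels'
time courses.  Shifting by +1 makes weights nonnegative (f in [0, 2]) so the
normalized-association machinery applies.  The spatial matrix e keeps f_uv
only for pairs of voxels that are spatial nearest neighbors (configurable
6/18/26-connectivity) and is the coherence term of the clustering objective.

Convention: the diagonal of f is 0.  All objective sums in this package
exclude u = v, and the kernel k-means solver adds its own diagonal shift, so
a single zero-diagonal convention keeps the three objective terms consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_nifti import ROIMask, VoxelTimeSeriesMatrix

logger = logging.getLogger(__name__)

#: Squared-distance cutoffs for the three standard 3D connectivities.
_CONNECTIVITY_R2 = {6: 1, 18: 2, 26: 3}


@dataclass
class SimilarityGraph:
    """Functional similarity graph over ROI voxels.

    Attributes
    ----------
    f : ndarray (N, N)
        Similarities f_uv = r_uv + 1 off-diagonal, 0 on the diagonal.
    r : ndarray (N, N)
        Pearson correlations (unit diagonal).
    e : scipy.sparse matrix (N, N)
        Spatial-neighbor similarities: f_uv where u, v adjacent, else 0.
    degree : ndarray (N,)
        d_u = sum_v f_uv.
    coords : ndarray (N, 3)
        Voxel grid coordinates in canonical order.
    """

    f: np.ndarray
    r: np.ndarray
    e: sp.spmatrix
    degree: np.ndarray
    coords: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.f.shape[0]


def correlation_matrix(ts: VoxelTimeSeriesMatrix) -> np.ndarray:
    """Pearson correlation matrix of the N voxel time courses.

    Zero-variance rows get correlation 0 with everything (and 1 with
    themselves) rather than NaN, with a warning.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need T >= 3 time points for correlations")
    X = ts.ts
    sd = X.std(axis=1)
    zv = sd == 0
    if zv.any():
        logger.warning("correlation_matrix: %d zero-variance rows -> r = 0", int(zv.sum()))
        X = X.copy()
        X[zv] = 0.0
        sd = sd.copy()
        sd[zv] = 1.0
    Xc = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (Xc @ Xc.T) / ts.n_timepoints
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def similarity_from_correlation(r: np.ndarray) -> np.ndarray:
    """Map correlations to nonnegative edge weights: f_uv = r_uv + 1.

    The diagonal is set to 0 (see module docstring)."""
    r = np.asarray(r, dtype=float)
    f = r + 1.0
    np.fill_diagonal(f, 0.0)
    return f


def spatial_adjacency(roi: ROIMask, f: np.ndarray, connectivity: int = 26) -> sp.csr_matrix:
    """Sparse e matrix: e_uv = f_uv iff u, v are spatial nearest neighbors.

    ``connectivity`` selects 6 (faces), 18 (faces+edges) or 26 (full 3x3x3
    shell).  Symmetric by construction.
    """
    if connectivity not in _CONNECTIVITY_R2:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    r2_max = _CONNECTIVITY_R2[connectivity]
    coords = roi.coords
    n = len(coords)
    if f.shape != (n, n):
        raise ValueError("f shape inconsistent with ROI voxel count")

    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and dx * dx + dy * dy + dz * dz <= r2_max
    ]
    rows, cols = [], []
    for u, (x, y, z) in enumerate(coords):
        for dx, dy, dz in offsets:
            v = index.get((x + dx, y + dy, z + dz))
            if v is not None:
                rows.append(u)
                cols.append(v)
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    e = sp.csr_matrix((f[rows, cols], (rows, cols)), shape=(n, n))
    return e


def build_similarity_graph(
    ts: VoxelTimeSeriesMatrix, roi: ROIMask, connectivity: int = 26
) -> SimilarityGraph:
    """Assemble the full SimilarityGraph (r, f, e, degrees) from time series."""
    r = correlation_matrix(ts)
    f = similarity_from_correlation(r)
    e = spatial_adjacency(roi, f, connectivity)
    degree = f.sum(axis=1)
    if np.any(degree <= 0):
        logger.warning("similarity graph has %d zero-degree nodes", int((degree <= 0).sum()))
    return SimilarityGraph(f=f, r=r, e=e, degree=degree, coords=roi.coords)
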