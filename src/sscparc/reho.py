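"""Regional homogeneity (ReHo): Kendall's coefficient of concordance W of
each voxel's time course with its spatial neighborhood.

For a voxel with K in-mask series (itself plus its neighbors) of length T,
each series is ranked over time (average/mid-ranks for ties), the per-time
rank sums R_t are formed, and

    W = 12 * sum_t (R_t - mean(R_t))^2 / (K^2 * (T^3 - T)).

W is 1 when all K series rank time points identically and near 0 for
independent series.  Neighbors outside the mask are dropped and K shrinks
accordingly; no tie-correction term is applied to the denominator (the usual
ReHo convention).  ReHo should be computed on unsmoothed data — spatial
smoothing trivially inflates neighborhood concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_nifti import ROIMask, Volume4D

logger = logging.getLogger(__name__)

_NBHD_R2 = {7: 1, 19: 2, 27: 3}


@dataclass
class ScalarMap:
    """A scalar value per in-mask voxel, kept as a 3D array plus its mask."""

    values: np.ndarray
    mask: ROIMask

    def in_mask_values(self) -> np.ndarray:
        """Values at the mask voxels, in canonical coords order."""
        return self.values[tuple(self.mask.coords.T)]


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's W of K series of length T (rows = series), midranks for ties."""
    series = np.asarray(series, dtype=float)
    k, t = series.shape
    if t < 3:
        raise ValueError("need T >= 3 time points for Kendall's W")
    if k == 1:
        return 0.0
    ranks = np.vstack([rankdata(row) for row in series])
    if np.any(ranks != np.round(ranks)):
        logger.debug("ties present; using midranks without tie correction")
    r_t = ranks.sum(axis=0)
    ss = float(((r_t - r_t.mean()) ** 2).sum())
    return 12.0 * ss / (k * k * (t**3 - t))


def compute_reho(vol: Volume4D, roi: ROIMask, neighborhood: int = 27) -> ScalarMap:
    """ReHo map over the ROI.

    Parameters
    ----------
    vol : Volume4D
        Unsmoothed 4D data on the same grid as ``roi``.
    roi : ROIMask
        Voxels to evaluate; out-of-mask neighbors are excluded (K shrinks).
    neighborhood : {7, 19, 27}
        Center plus face (7), face+edge (19) or full 3x3x3 (27) neighbors.

    Returns
    -------
    ScalarMap with W in [0, 1] at each in-mask voxel; isolated voxels
    (K = 1) get W = 0 with a warning.
    """
    if neighborhood not in _NBHD_R2:
        raise ValueError(f"neighborhood must be 7, 19 or 27, got {neighborhood}")
    if vol.n_timepoints < 3:
        raise ValueError("need T >= 3 time points for ReHo")
    if vol.shape3d != roi.mask.shape:
        raise ValueError("volume and mask grids differ")
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")

    r2_max = _NBHD_R2[neighborhood]
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if dx * dx + dy * dy + dz * dz <= r2_max
    ]  # includes (0,0,0): the center voxel

    # Rank every in-mask series once; neighborhoods then just sum rank rows.
    ranks3d = np.zeros((*vol.shape3d, vol.n_timepoints))
    for x, y, z in roi.coords:
        ranks3d[x, y, z] = rankdata(vol.data[x, y, z])

    shape = roi.mask.shape
    values = np.zeros(shape)
    t = vol.n_timepoints
    denom_base = t**3 - t
    n_isolated = 0
    for x, y, z in roi.coords:
        r_t = np.zeros(t)
        k = 0
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2] and roi.mask[nx, ny, nz]:
                r_t += ranks3d[nx, ny, nz]
                k += 1
        if k == 1:
            n_isolated += 1
            values[x, y, z] = 0.0
            continue
        ss = float(((r_t - r_t.mean()) ** 2).sum())
        values[x, y, z] = 12.0 * ss / (k * k * denom_base)
    if n_isolated:
        logger.warning("%d isolated voxels (K = 1) assigned ReHo 0", n_isolated)
    return ScalarMap(values=values, mask=roi)
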