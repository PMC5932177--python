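"""Seed-based functional connectivity maps and voxelwise group statistics.

For a seed region, the FC map is the Pearson correlation of every in-mask
voxel's time course with the seed-mean time course, Fisher r-to-z
transformed (z = atanh r) for group-level statistics.  Group maps are plain
voxelwise one-sample or paired t-tests; no cluster-level correction is
applied and outputs are explicitly uncorrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_nifti import ROIMask, Volume4D

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7
#: cap reported in place of an infinite t (zero sample variance)
T_CAP = 1e6


@dataclass
class FCMap:
    """Seed-based correlation and Fisher-z maps over a brain mask."""

    r_map: np.ndarray  # 3D, zero outside mask
    z_map: np.ndarray
    seed_label: int = 0
    mask: ROIMask | None = None


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| = 1 clipped to +/-(1 - 1e-7) (logged)."""
    r = np.asarray(r, dtype=float)
    n_clip = int(np.sum(np.abs(r) >= 1.0))
    if n_clip:
        logger.warning("clipping %d |r| >= 1 values before Fisher transform", n_clip)
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def seed_fc_map(
    vol: Volume4D, seed_voxels: np.ndarray, brain_mask: ROIMask, seed_label: int = 0
) -> FCMap:
    """Correlate every in-mask voxel with the mean time course of the seed.

    ``seed_voxels`` is an (M, 3) array of grid coordinates.  Zero-variance
    voxels get r = 0; a zero-variance seed mean is an error.
    """
    seed_voxels = np.asarray(seed_voxels)
    if seed_voxels.ndim != 2 or seed_voxels.shape[0] == 0:
        raise ValueError("seed must be a nonempty (M, 3) coordinate array")
    if vol.shape3d != brain_mask.mask.shape:
        raise ValueError("volume and brain mask grids differ")
    seed_ts = vol.data[tuple(seed_voxels.T)].mean(axis=0)
    sd_seed = seed_ts.std()
    if sd_seed == 0:
        raise ValueError("zero-variance seed mean time course")
    seed_c = (seed_ts - seed_ts.mean()) / sd_seed

    X = vol.data[tuple(brain_mask.coords.T)]
    sd = X.std(axis=1)
    zv = sd == 0
    sd_safe = np.where(zv, 1.0, sd)
    Xc = (X - X.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    r = (Xc @ seed_c) / vol.n_timepoints
    r[zv] = 0.0
    r = np.clip(r, -1.0, 1.0)

    r_map = np.zeros(vol.shape3d)
    r_map[tuple(brain_mask.coords.T)] = r
    z_map = np.zeros(vol.shape3d)
    z_map[tuple(brain_mask.coords.T)] = fisher_z(r)
    return FCMap(r_map=r_map, z_map=z_map, seed_label=seed_label, mask=brain_mask)


def voxelwise_ttest(
    z_maps_a: list[np.ndarray],
    z_maps_b: list[np.ndarray] | None = None,
    paired: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample (B absent) or paired t-test on Fisher-z maps.

    Returns (t_map, p_map), both 3D, p uncorrected.  Voxels with zero sample
    variance but nonzero mean get t capped at +/-T_CAP (flagged in the log);
    zero variance and zero mean give t = 0.
    """
    if len(z_maps_a) < 2:
        raise ValueError("need at least 2 maps")
    A = np.stack(z_maps_a)
    if z_maps_b is not None:
        if not paired:
            raise NotImplementedError("only paired two-sample maps are supported")
        if len(z_maps_b) != len(z_maps_a):
            raise ValueError("paired test needs matched lists of equal length")
        A = A - np.stack(z_maps_b)
    n = A.shape[0]
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    n_cap = int(np.sum(zero_var & (mean != 0)))
    if n_cap:
        logger.warning("%d zero-variance voxels with nonzero mean: t capped at %g", n_cap, T_CAP)
    t = np.where(zero_var, np.where(mean == 0, 0.0, np.sign(mean) * T_CAP), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return t, p
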