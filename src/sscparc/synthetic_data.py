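"""Synthetic fMRI-like subjects and cohorts with planted subregions.

Each subject has an ellipsoidal ROI partitioned into k spatially contiguous
subregions (discrete Voronoi cells of k well-separated seed voxels).  Every
voxel's time course is its subregion's latent band-limited Gaussian signal,
scaled by snr, plus unit white noise, band-pass filtered to the resting-state
band (zero-phase order-4 Butterworth).  A prior atlas is derived from the
ground truth by shifting the generating seeds and randomly reassigning a
fraction of boundary voxels — a deliberately imperfect stand-in for a
cytoarchitectonic atlas that is misaligned with function at the boundaries.
Cohorts share a template truth; each subject's boundaries are independently
jittered to emulate inter-subject variability.

The generator captures what the parcellation method assumes — functionally
homogeneous, spatially coherent subregions — and nothing it does not need:
no hemodynamics, motion, or physiological artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import butter, sosfiltfilt

from .io_nifti import LabelMap, ROIMask, Volume4D, roi_from_mask

logger = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Study-condition parameters of the generator.

    Defaults mirror a typical high-resolution resting-state acquisition:
    190 retained volumes at TR = 3 s, 0.01-0.08 Hz band, 1.5 mm isotropic
    voxels, k = 3 target subregions, snr 1 (latent-signal sd equals noise
    sd before filtering), and 1-voxel boundary jitter / prior mismatch.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    k: int = 3
    n_timepoints: int = 190
    tr_s: float = 3.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    snr: float = 1.0
    boundary_jitter_vox: int = 1
    prior_mismatch_vox: int = 1
    boundary_flip_frac: float = 0.3
    noise_smooth_sigma_vox: float = 0.0
    voxel_size_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 time points")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.boundary_jitter_vox < 0 or self.prior_mismatch_vox < 0:
            raise ValueError("jitters must be >= 0")


@dataclass
class SyntheticSubject:
    """One simulated subject: 4D volume, ground truth, prior atlas, ROI."""

    volume: Volume4D
    truth: LabelMap
    prior_atlas: LabelMap
    roi: ROIMask


def _ellipsoid_roi(grid_shape: tuple[int, int, int]) -> ROIMask:
    """Centered ellipsoidal blob filling most of the grid; >= 200 voxels."""
    shape = np.asarray(grid_shape)
    center = (shape - 1) / 2.0
    semi = np.maximum((shape - 1) / 2.0 - 0.5, 0.5)
    xx, yy, zz = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    )
    mask = d2 <= 1.0
    if mask.sum() < 200:
        raise ValueError(
            f"grid {tuple(grid_shape)} too small: ellipsoid has {int(mask.sum())} "
            "voxels, need >= 200"
        )
    return roi_from_mask(mask)


def _farthest_point_seeds(roi: ROIMask, k: int) -> np.ndarray:
    """k well-separated seed voxels by deterministic farthest-point sampling."""
    coords = roi.coords.astype(float)
    centroid = coords.mean(axis=0)
    first = int(np.argmin(((coords - centroid) ** 2).sum(axis=1)))
    seeds = [first]
    dist = ((coords - coords[first]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, ((coords - coords[nxt]) ** 2).sum(axis=1))
    return roi.coords[seeds]


def _voronoi_labels(roi: ROIMask, seed_coords: np.ndarray) -> np.ndarray:
    """Label each ROI voxel by its nearest seed (lowest index on ties)."""
    d2 = ((roi.coords[:, None, :] - seed_coords[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(np.int32) + 1


def _enforce_connectivity(labels: np.ndarray, roi: ROIMask, k: int) -> np.ndarray:
    """Make every label one 6-connected component by absorbing stray pieces
    into an adjacent label (iterated until stable)."""
    vol = roi.labels_to_volume(labels)
    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(20):
        changed = False
        for lab in range(1, k + 1):
            comp, n_comp = ndimage.label(vol == lab, structure=struct)
            if n_comp <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n_comp + 1):
                if c == keep:
                    continue
                piece = comp == c
                dil = ndimage.binary_dilation(piece, structure=struct) & roi.mask & ~piece
                nb = vol[dil]
                nb = nb[nb != lab]
                new_lab = int(np.bincount(nb).argmax()) if len(nb) else (lab % k) + 1
                vol[piece] = new_lab
                changed = True
        if not changed:
            break
    return vol[tuple(roi.coords.T)].astype(np.int32)


def _jitter_seeds(
    seed_coords: np.ndarray, roi: ROIMask, amount: int, rng: np.random.Generator
) -> np.ndarray:
    """Displace each seed uniformly within a Chebyshev ball, staying in the ROI."""
    if amount == 0:
        return seed_coords.copy()
    out = seed_coords.copy()
    for i in range(len(out)):
        for _ in range(50):
            off = rng.integers(-amount, amount + 1, size=3)
            cand = out[i] + off
            if (
                np.all(cand >= 0)
                and np.all(cand < roi.mask.shape)
                and roi.mask[tuple(cand)]
            ):
                out[i] = cand
                break
    return out


def _boundary_flips(
    labels: np.ndarray, roi: ROIMask, frac: float, rng: np.random.Generator, k: int
) -> np.ndarray:
    """Randomly reassign a fraction of boundary voxels to an adjacent label,
    never emptying a label."""
    vol = roi.labels_to_volume(labels)
    struct = ndimage.generate_binary_structure(3, 1)
    out = labels.copy()
    # boundary voxels: in ROI, with a 6-neighbor of a different nonzero label
    boundary = []
    neighbor_labels: list[list[int]] = []
    for idx, (x, y, z) in enumerate(roi.coords):
        lab = vol[x, y, z]
        nbs = set()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < vol.shape[0] and 0 <= ny < vol.shape[1] and 0 <= nz < vol.shape[2]:
                v = vol[nx, ny, nz]
                if v not in (0, lab):
                    nbs.add(int(v))
        if nbs:
            boundary.append(idx)
            neighbor_labels.append(sorted(nbs))
    _ = struct
    if not boundary:
        return out
    n_flip = int(round(frac * len(boundary)))
    chosen = rng.choice(len(boundary), size=n_flip, replace=False) if n_flip else []
    counts = np.bincount(out, minlength=k + 1)
    for ci in chosen:
        idx = boundary[ci]
        if counts[out[idx]] <= 1:
            continue
        new_lab = int(rng.choice(neighbor_labels[ci]))
        counts[out[idx]] -= 1
        counts[new_lab] += 1
        out[idx] = new_lab
    return out


def _bandpass_sos(band_hz: tuple[float, float], tr_s: float):
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    low, high = band_hz
    return butter(4, [low / nyq, high / nyq], btype="band", output="sos")


_BURN_IN = 64  # samples dropped at each end to kill filter edge transients


def _simulate_timeseries(
    labels: np.ndarray, params: SimParams, rng: np.random.Generator, roi: ROIMask
) -> np.ndarray:
    """N x T voxel series: snr * latent(subregion) + white noise, band-passed.

    Series are simulated with a burn-in margin at both ends and trimmed to T
    afterwards, so the zero-phase filter's edge transients (which leak power
    outside the passband) never reach the delivered data.
    """
    t = params.n_timepoints
    t_ext = t + 2 * _BURN_IN
    sos = _bandpass_sos(params.band_hz, params.tr_s)
    latents = {}
    for lab in range(1, params.k + 1):
        raw = rng.standard_normal(t_ext)
        filt = sosfiltfilt(sos, raw)
        latents[lab] = filt / filt.std()
    noise = rng.standard_normal((len(labels), t_ext))
    if params.noise_smooth_sigma_vox > 0:
        # spatially smooth each time frame of the noise field (in-ROI only)
        vol = np.zeros((*roi.mask.shape, t_ext))
        vol[tuple(roi.coords.T)] = noise
        for i in range(t_ext):
            vol[..., i] = ndimage.gaussian_filter(vol[..., i], params.noise_smooth_sigma_vox)
        noise = vol[tuple(roi.coords.T)]
        noise /= noise.std(axis=1, keepdims=True)
    ts = np.stack([params.snr * latents[lab] for lab in labels]) + noise
    ts = sosfiltfilt(sos, ts, axis=1)
    return ts[:, _BURN_IN:_BURN_IN + t]


def _perturbed_prior(
    truth_labels: np.ndarray,
    truth_seeds: np.ndarray,
    roi: ROIMask,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Atlas stand-in: truth with seed-shifted boundaries + random boundary
    reassignments; every label stays nonempty."""
    if params.prior_mismatch_vox == 0:
        return truth_labels.copy()
    prior_seeds = _jitter_seeds(truth_seeds, roi, params.prior_mismatch_vox, rng)
    prior_labels = _voronoi_labels(roi, prior_seeds)
    prior_labels = _boundary_flips(
        prior_labels, roi, params.boundary_flip_frac, rng, params.k
    )
    for lab in range(1, params.k + 1):
        if not np.any(prior_labels == lab):
            prior_labels[truth_labels == lab] = lab
    return prior_labels


def generate_subject(
    params: SimParams,
    subject_seed: int,
    _template_seeds: np.ndarray | None = None,
    _shared_prior: np.ndarray | None = None,
) -> SyntheticSubject:
    """Generate one synthetic subject; byte-identical for fixed arguments.

    The ROI and the template subregion seeds are pure functions of the grid;
    all randomness (boundary jitter, prior mismatch, signals, noise) comes
    from ``subject_seed``.  The prior perturbation uses an rng stream
    separate from the signal stream so a cohort-shared prior
    (``_shared_prior``, a length-N label vector) leaves the subject's truth
    and time series unchanged.
    """
    roi = _ellipsoid_roi(params.grid_shape)
    if _template_seeds is None:
        _template_seeds = _farthest_point_seeds(roi, params.k)
    rng = np.random.default_rng([subject_seed, 0])

    truth_seeds = _jitter_seeds(_template_seeds, roi, params.boundary_jitter_vox, rng)
    truth_labels = _enforce_connectivity(_voronoi_labels(roi, truth_seeds), roi, params.k)

    if _shared_prior is not None:
        prior_labels = _shared_prior.copy()
    else:
        prior_rng = np.random.default_rng([subject_seed, 1])
        prior_labels = _perturbed_prior(truth_labels, truth_seeds, roi, params, prior_rng)

    ts = _simulate_timeseries(truth_labels, params, rng, roi)
    data = np.zeros((*params.grid_shape, params.n_timepoints))
    data[tuple(roi.coords.T)] = ts

    vs = np.full(3, params.voxel_size_mm)
    affine = np.diag([*vs, 1.0])
    names = {i: f"sub{i}" for i in range(1, params.k + 1)}
    return SyntheticSubject(
        volume=Volume4D(data=data, voxel_size_mm=vs, affine=affine, tr_s=params.tr_s),
        truth=LabelMap(roi.labels_to_volume(truth_labels), vs, affine, dict(names)),
        prior_atlas=LabelMap(roi.labels_to_volume(prior_labels), vs, affine, dict(names)),
        roi=roi,
    )


def generate_cohort(n_subjects: int, params: SimParams) -> list[SyntheticSubject]:
    """A cohort sharing one template truth, boundaries jittered per subject.

    Subject i uses subject_seed = params.seed + i, so cohorts are
    reproducible and subjects mutually independent given the template.  All
    subjects share one prior atlas, derived once from the unjittered
    template truth — mirroring a study design where a single fixed atlas is
    applied to every participant; inter-subject variability lives entirely
    in the functional data and true boundaries.
    """
    if n_subjects < 1:
        raise ValueError("need at least 1 subject")
    roi = _ellipsoid_roi(params.grid_shape)
    template = _farthest_point_seeds(roi, params.k)
    template_truth = _enforce_connectivity(
        _voronoi_labels(roi, template), roi, params.k
    )
    prior_rng = np.random.default_rng([params.seed, 2])
    shared_prior = _perturbed_prior(template_truth, template, roi, params, prior_rng)
    return [
        generate_subject(params, params.seed + i, _template_seeds=template,
                         _shared_prior=shared_prior)
        for i in range(n_subjects)
    ]
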