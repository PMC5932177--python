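"""Quantitative evaluation of parcellations: Dice overlap, modified
silhouette width, subregion volumes, cohort probability maps, maximum
probability maps (MPM), and cross-subject label entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_nifti import LabelMap

logger = logging.getLogger(__name__)


@dataclass
class ProbabilityMap:
    """Per-voxel, per-label frequency across a cohort.

    ``probs[x, y, z, i]`` is the fraction of the full cohort assigning label
    ``labels_order[i]`` to the voxel.  Per voxel the frequencies sum to the
    fraction of subjects labeling it at all (<= 1).
    """

    probs: np.ndarray  # (X, Y, Z, k)
    n_subjects: int
    labels_order: list[int]
    label_names: dict[int, str] = field(default_factory=dict)


@dataclass
class SIResult:
    """Modified silhouette width with its per-cluster intermediates."""

    si: float
    per_cluster: list[tuple[float, float, int]]  # (a_c, b_c, n_c)


@dataclass
class EntropyResult:
    """Average discrete label entropy across evaluated voxels."""

    h_mean: float
    h_map: np.ndarray  # 3D; NaN where no subject assigned any label
    log_base: str = "e"
    n_voxels: int = 0


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X ∩ Y| / (|X| + |Y|) of two voxel sets.

    Accepts boolean masks (any shape, matching) or 1D index arrays.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.dtype == bool or y.dtype == bool:
        nx, ny = int(x.sum()), int(y.sum())
        ninter = int((x & y).sum())
    else:
        sx, sy = set(map(int, x.ravel())), set(map(int, y.ravel()))
        nx, ny = len(sx), len(sy)
        ninter = len(sx & sy)
    if nx + ny == 0:
        raise ValueError("both sets empty: Dice undefined")
    return 2.0 * ninter / (nx + ny)


def modified_si(labels: np.ndarray, f: np.ndarray) -> SIResult:
    """Similarity-based silhouette width of a labeling on similarity f.

    a_c = mean within-cluster similarity over ordered pairs (u != v);
    b_c = mean cluster-to-rest similarity over ordered cross pairs;
    SI = mean over clusters of (a_c - b_c) / max(a_c, b_c) — in [-1, 1],
    higher means more functionally homogeneous clusters.
    """
    labels = np.asarray(labels)
    n = len(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ValueError("SI undefined for a single cluster covering all voxels")
    per_cluster: list[tuple[float, float, int]] = []
    vals = []
    for c in ks:
        idx = np.flatnonzero(labels == c)
        n_c = len(idx)
        if n_c < 2:
            raise ValueError(f"singleton cluster {c}: a_c undefined")
        sub = f[np.ix_(idx, idx)]
        a_c = (float(sub.sum()) - float(np.trace(sub))) / (n_c * (n_c - 1))
        rest = np.flatnonzero(labels != c)
        b_c = float(f[np.ix_(idx, rest)].sum()) / (n_c * (n - n_c))
        m = max(a_c, b_c)
        vals.append((a_c - b_c) / m if m > 0 else 0.0)
        per_cluster.append((a_c, b_c, n_c))
    return SIResult(si=float(np.mean(vals)), per_cluster=per_cluster)


def roi_volume(lm: LabelMap) -> dict[int, dict[str, float]]:
    """Per-label voxel counts and volumes (count x voxel volume, mm^3)."""
    vox_mm3 = float(np.prod(lm.voxel_size_mm))
    report: dict[int, dict[str, float]] = {}
    labs = lm.present_labels
    if not labs:
        logger.warning("label map has no foreground labels; empty volume report")
    for lab in labs:
        count = int(np.sum(lm.labels == lab))
        report[lab] = {
            "voxels": count,
            "volume_mm3": count * vox_mm3,
            "voxel_volume_mm3": vox_mm3,
        }
    return report


def probability_maps(cohort_labels: list[LabelMap], n_subjects: int | None = None) -> ProbabilityMap:
    """Per-voxel label frequencies across a cohort of label maps.

    The denominator is the full cohort size, so voxels labeled in only some
    subjects have frequencies summing to < 1.
    """
    if not cohort_labels:
        raise ValueError("empty cohort")
    shape = cohort_labels[0].labels.shape
    for lm in cohort_labels:
        if lm.labels.shape != shape:
            raise ValueError("cohort label maps are on different grids")
    if n_subjects is None:
        n_subjects = len(cohort_labels)
    all_labels = sorted(set().union(*(lm.present_labels for lm in cohort_labels)))
    probs = np.zeros((*shape, len(all_labels)))
    for lm in cohort_labels:
        for i, lab in enumerate(all_labels):
            probs[..., i] += lm.labels == lab
    probs /= n_subjects
    names: dict[int, str] = {}
    for lm in cohort_labels:
        names.update(lm.label_names)
    return ProbabilityMap(
        probs=probs, n_subjects=n_subjects, labels_order=all_labels, label_names=names
    )


def build_mpm(
    pm: ProbabilityMap,
    cum_thresh: float = 0.60,
    single_thresh: float = 0.50,
    voxel_size_mm: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> LabelMap:
    """Maximum probability map from cohort label frequencies.

    A voxel enters the map iff its cumulative label frequency is >= ``cum_thresh``
    or any single label's frequency is >= ``single_thresh``; it then takes the
    arg-max label; exact ties go to the tied label with the highest mean
    frequency over the 3x3x3 neighborhood, residual ties to the lowest label.
    """
    probs = pm.probs
    shape = probs.shape[:3]
    cum = probs.sum(axis=3)
    mx = probs.max(axis=3)
    include = (cum >= cum_thresh) | (mx >= single_thresh)

    # neighborhood mean frequency per label, for tie-breaking
    from scipy import ndimage

    nb_mean = np.stack(
        [ndimage.uniform_filter(probs[..., i], size=3, mode="constant") for i in range(probs.shape[3])],
        axis=3,
    )

    out = np.zeros(shape, dtype=np.int32)
    n_residual_ties = 0
    for x, y, z in zip(*np.nonzero(include)):
        p = probs[x, y, z]
        top = p.max()
        tied = np.flatnonzero(p == top)
        if len(tied) == 1:
            winner = tied[0]
        else:
            nb = nb_mean[x, y, z, tied]
            best = np.flatnonzero(nb == nb.max())
            if len(best) > 1:
                n_residual_ties += 1
            winner = tied[best[0]]  # tied labels ascend, so lowest label wins residuals
        out[x, y, z] = pm.labels_order[winner]
    if n_residual_ties:
        logger.warning("%d residual MPM ties resolved to the lowest label", n_residual_ties)

    if voxel_size_mm is None:
        voxel_size_mm = np.ones(3)
    if affine is None:
        affine = np.eye(4)
    return LabelMap(
        labels=out, voxel_size_mm=voxel_size_mm, affine=affine, label_names=dict(pm.label_names)
    )


def discrete_entropy(pm: ProbabilityMap, log_base: str = "e") -> EntropyResult:
    """Average per-voxel Shannon entropy of label assignment across a cohort.

    Per-voxel frequencies are renormalized over the subjects that assign any
    label at that voxel (the entropy presupposes a distribution over the k
    labels); voxels labeled by no subject are skipped.  H(u) = 0 means the
    cohort is unanimous; log(k) means uniform disagreement.  Lower mean
    entropy = higher cross-subject consistency.
    """
    if log_base not in ("e", "2"):
        raise ValueError("log_base must be 'e' or '2'")
    log = np.log if log_base == "e" else np.log2
    probs = pm.probs
    tot = probs.sum(axis=3)
    h_map = np.full(probs.shape[:3], np.nan)
    mask = tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pr = probs[mask] / tot[mask][:, None]
        terms = np.where(pr > 0, pr * log(pr), 0.0)
    h_map[mask] = -terms.sum(axis=1)
    n_vox = int(mask.sum())
    h_mean = float(np.nanmean(h_map)) if n_vox else 0.0
    return EntropyResult(h_mean=h_mean, h_map=h_map, log_base=log_base, n_voxels=n_vox)
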