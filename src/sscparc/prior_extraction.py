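"""Extraction of the k prior seed regions from an atlas label map.

Rather than trusting atlas boundaries wholesale, the parcellation anchors
each cluster to one *small, functionally homogeneous* region per atlas
subregion.  Each subregion is watershed-segmented on its (negated) ReHo map,
so basins grow around local maxima of regional homogeneity; one candidate
basin per subregion is then chosen so that the joint MinMaxCut score

    Mcut = sum_i sum_{j != i}  [ sum_{u in p_i, v in p_j} f_uv ]
                              / [ sum_{u,v in p_i, u != v} f_uv ]

is minimal — i.e. the selected triple is maximally homogeneous within and
separated between.  Sums run over ordered pairs (u, v), u != v.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .io_nifti import LabelMap, ROIMask
from .reho import ScalarMap

logger = logging.getLogger(__name__)


@dataclass
class PriorSet:
    """k disjoint prior regions as voxel-index sets (canonical coords order)."""

    regions: list[np.ndarray]  # each an int index array into coords order
    source_labels: list[int] = field(default_factory=list)
    mcut: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.regions)

    def prior_of_voxel(self, n_voxels: int) -> np.ndarray:
        """Length-N vector: 1-based prior index per voxel, 0 if in no prior."""
        out = np.zeros(n_voxels, dtype=np.int32)
        for i, reg in enumerate(self.regions, start=1):
            out[reg] = i
        return out


def watershed_candidates(
    reho: ScalarMap,
    atlas: LabelMap,
    roi: ROIMask,
    min_size: int = 5,
    h: float = 0.05,
) -> dict[int, list[np.ndarray]]:
    """Per atlas subregion, candidate voxel sets from watershed on -ReHo.

    Markers are the ReHo local maxima after h-maxima suppression (height
    ``h``), so each basin contains one prominent homogeneity peak.
    Candidates smaller than ``min_size`` voxels are dropped; if a subregion
    loses all its basins to the size filter, its largest basin is kept with
    a warning.  Returns voxel-index arrays in canonical coords order.
    """
    if atlas.labels.shape != roi.mask.shape:
        raise ValueError("atlas and ROI grids differ")
    coords = roi.coords
    index_vol = np.full(roi.mask.shape, -1, dtype=np.int64)
    index_vol[tuple(coords.T)] = np.arange(len(coords))

    labels_in_roi = atlas.labels[tuple(coords.T)]
    out: dict[int, list[np.ndarray]] = {}
    for lab in atlas.present_labels:
        sub_mask = (atlas.labels == lab) & roi.mask
        n_sub = int(sub_mask.sum())
        if n_sub == 0:
            raise ValueError(f"atlas subregion {lab} has no voxels inside the ROI")

        vals = np.where(sub_mask, reho.values, 0.0)
        # h-maxima suppression keeps only peaks with prominence >= h
        peaks = h_maxima(vals, h) & sub_mask
        markers, n_mark = ndimage.label(peaks)
        if n_mark <= 1:
            # constant or single-peak field: the whole subregion is one basin
            basins = sub_mask.astype(np.int32)
            basins[~sub_mask] = 0
            seg = basins
        else:
            seg = watershed(-vals, markers=markers, mask=sub_mask)

        cand: list[np.ndarray] = []
        sizes: list[int] = []
        for b in np.unique(seg):
            if b == 0:
                continue
            vox = index_vol[(seg == b) & sub_mask]
            vox = np.sort(vox[vox >= 0])
            if len(vox) == 0:
                continue
            sizes.append(len(vox))
            if len(vox) >= min_size:
                cand.append(vox)
        if not cand:
            # fallback: keep the largest basin even if undersized
            all_basins = [
                np.sort(index_vol[(seg == b) & sub_mask])
                for b in np.unique(seg)
                if b != 0
            ]
            all_basins = [v[v >= 0] for v in all_basins if len(v) > 0]
            if not all_basins:
                cand = [np.sort(index_vol[sub_mask][index_vol[sub_mask] >= 0])]
            else:
                cand = [max(all_basins, key=len)]
            logger.warning(
                "atlas label %d: all basins below min_size=%d, keeping largest (%d voxels)",
                lab, min_size, len(cand[0]),
            )
        out[lab] = cand
        _ = labels_in_roi  # kept for clarity; per-voxel labels available if needed
    return out


def mcut_score(regions: list[np.ndarray], f: np.ndarray) -> float:
    """MinMaxCut of disjoint regions on similarity matrix f (ordered pairs).

    Lower is better: numerators are between-region similarity sums, each
    divided by its region's within-similarity sum.
    """
    k = len(regions)
    if k < 2:
        raise ValueError("need at least 2 regions")
    regions = [np.asarray(r, dtype=np.int64) for r in regions]
    all_idx = np.concatenate(regions)
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("regions must be disjoint")

    within = []
    for reg in regions:
        if len(reg) < 2:
            raise ValueError("degenerate prior region: fewer than 2 voxels")
        sub = f[np.ix_(reg, reg)]
        w = float(sub.sum() - np.trace(sub))  # ordered pairs, u != v
        if w <= 0:
            raise ValueError("degenerate prior region: zero within-similarity")
        within.append(w)

    total = 0.0
    for i, pi in enumerate(regions):
        between_i = 0.0
        for j, pj in enumerate(regions):
            if i == j:
                continue
            between_i += float(f[np.ix_(pi, pj)].sum())
        total += between_i / within[i]
    return total


def _within_density(reg: np.ndarray, f: np.ndarray) -> float:
    if len(reg) < 2:
        return -np.inf
    sub = f[np.ix_(reg, reg)]
    return float(sub.sum() - np.trace(sub)) / (len(reg) * (len(reg) - 1))


def select_prior_regions(
    candidates: dict[int, list[np.ndarray]],
    f: np.ndarray,
    strategy: str = "exhaustive",
    max_combinations: int = 100_000,
) -> PriorSet:
    """Choose one candidate per atlas label minimizing the joint Mcut.

    ``exhaustive`` enumerates every one-per-label combination (errors past
    ``max_combinations``); ``greedy`` starts from the densest candidate per
    label and hill-climbs one label at a time to a local minimum.  Ties are
    broken toward larger total prior size, then lower label order.
    """
    labels = sorted(candidates)
    if any(len(candidates[lab]) == 0 for lab in labels):
        raise ValueError("every atlas label needs at least one candidate")
    cand_lists = [candidates[lab] for lab in labels]

    def score(choice: tuple[int, ...]) -> float:
        regs = [cand_lists[i][c] for i, c in enumerate(choice)]
        return mcut_score(regs, f)

    def total_size(choice: tuple[int, ...]) -> int:
        return sum(len(cand_lists[i][c]) for i, c in enumerate(choice))

    if strategy == "exhaustive":
        n_combo = int(np.prod([len(c) for c in cand_lists]))
        if n_combo > max_combinations:
            raise ValueError(
                f"{n_combo} combinations exceed the exhaustive cap "
                f"({max_combinations}); use strategy='greedy'"
            )
        best: tuple[int, ...] | None = None
        best_val = np.inf
        for choice in itertools.product(*(range(len(c)) for c in cand_lists)):
            val = score(choice)
            if val < best_val - 1e-15 or (
                abs(val - best_val) <= 1e-15
                and best is not None
                and (
                    total_size(choice) > total_size(best)
                    or (total_size(choice) == total_size(best) and choice < best)
                )
            ):
                best, best_val = choice, val
        assert best is not None
    elif strategy == "greedy":
        best = tuple(
            int(np.argmax([_within_density(c, f) for c in clist]))
            for clist in cand_lists
        )
        best_val = score(best)
        improved = True
        while improved:
            improved = False
            for i in range(len(labels)):
                for c in range(len(cand_lists[i])):
                    if c == best[i]:
                        continue
                    trial = best[:i] + (c,) + best[i + 1 :]
                    val = score(trial)
                    if val < best_val - 1e-15:
                        best, best_val = trial, val
                        improved = True
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    regions = [cand_lists[i][c] for i, c in enumerate(best)]
    return PriorSet(regions=regions, source_labels=labels, mcut=best_val)


def extract_priors(
    reho: ScalarMap,
    atlas: LabelMap,
    roi: ROIMask,
    f: np.ndarray,
    min_size: int = 5,
    h: float = 0.05,
    strategy: str = "exhaustive",
) -> PriorSet:
    """Full prior extraction: watershed candidates then Mcut selection."""
    cands = watershed_candidates(reho, atlas, roi, min_size=min_size, h=h)
    try:
        return select_prior_regions(cands, f, strategy=strategy)
    except ValueError as err:
        if "exhaustive cap" in str(err):
            logger.warning("falling back to greedy prior selection: %s", err)
            return select_prior_regions(cands, f, strategy="greedy")
        raise
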