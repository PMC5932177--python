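"""NIfTI I/O and conversion between 4D volumes and per-ROI time-series
matrices.

Every module in the package indexes ROI voxels by one canonical order: the
lexicographic sort of their (x, y, z) grid coordinates.  That order is fixed
here, in :func:`roi_from_mask`, and carried around explicitly as
``ROIMask.coords`` so the similarity graph, the priors, and the output label
maps can never silently disagree about which row is which voxel.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Volume4D:
    """A 4D (x, y, z, t) scalar volume with grid geometry and sampling rate.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel time series, T >= 2.
    voxel_size_mm : ndarray, shape (3,)
        Voxel edge lengths in mm, all positive.
    affine : ndarray, shape (4, 4)
        Grid-to-world map.
    tr_s : float
        Repetition time in seconds.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    affine: np.ndarray
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelMap:
    """3D integer label image; 0 is background."""

    labels: np.ndarray
    voxel_size_mm: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D labels, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def present_labels(self) -> list[int]:
        """Sorted nonzero labels present in the map."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]


@dataclass
class ROIMask:
    """Boolean ROI with the canonical ordered voxel coordinate list.

    ``coords`` is the lexicographic (x, y, z) sort of the in-mask voxels and
    defines the voxel index 0..N-1 used by every matrix in the package.
    """

    mask: np.ndarray
    coords: np.ndarray  # (N, 3) int

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def labels_to_volume(self, labels: np.ndarray, fill: int = 0) -> np.ndarray:
        """Scatter a length-N label vector back onto the 3D grid."""
        out = np.full(self.mask.shape, fill, dtype=np.int32)
        out[tuple(self.coords.T)] = labels
        return out


@dataclass
class VoxelTimeSeriesMatrix:
    """N x T matrix of voxel time courses in ``coords`` order.

    ``zero_variance`` flags rows with constant signal; downstream correlation
    handles them by defining their correlations as 0.
    """

    ts: np.ndarray
    coords: np.ndarray
    tr_s: float = 1.0
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=float)
        if self.ts.ndim != 2:
            raise ValueError("ts must be 2D (N voxels x T time points)")
        if not np.all(np.isfinite(self.ts)):
            raise ValueError("time series contain non-finite values")
        if self.zero_variance is None:
            self.zero_variance = self.ts.std(axis=1) == 0

    @property
    def n_voxels(self) -> int:
        return self.ts.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.ts.shape[1]


def _check_nan(data: np.ndarray, allow_nan: bool, what: str) -> np.ndarray:
    n_nan = int(np.isnan(data).sum())
    if n_nan == 0:
        return data
    if not allow_nan:
        raise ValueError(
            f"{what} contains {n_nan} NaN values; pass allow_nan=True to zero-fill"
        )
    logger.warning("%s: zero-filling %d NaN values", what, n_nan)
    return np.nan_to_num(data, nan=0.0)


def read_volume4d(path: str | os.PathLike, allow_nan: bool = False) -> Volume4D:
    """Load a 4D NIfTI volume.

    NaNs are rejected unless ``allow_nan`` (then zero-filled with a logged
    count) because they propagate silently through Pearson correlations.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D: {path}")
    data = _check_nan(data, allow_nan, f"volume {path}")
    zooms = img.header.get_zooms()
    if not all(np.isfinite(zooms[:3])):
        raise ValueError(f"non-finite voxel sizes in header: {path}")
    tr = float(zooms[3]) if len(zooms) > 3 and np.isfinite(zooms[3]) and zooms[3] > 0 else 1.0
    return Volume4D(
        data=data,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        affine=img.affine,
        tr_s=tr,
    )


def write_volume4d(vol: Volume4D, path: str | os.PathLike) -> str:
    """Write a Volume4D to NIfTI, preserving voxel size and TR in the header."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_s))
    nib.save(img, str(path))
    return str(path)


def _sidecar_path(path: str) -> str:
    base = path
    for suf in (".nii.gz", ".nii"):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    return base + "_labels.tsv"


def read_labelmap(path: str | os.PathLike) -> LabelMap:
    """Load a 3D integer label map; names from an optional TSV sidecar.

    The sidecar is a headered 2-column TSV (label, name) next to the image.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D label map, got {data.ndim}D: {path}")
    fdata = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(fdata)):
        raise ValueError(f"label map contains non-finite values: {path}")
    if not np.allclose(fdata, np.round(fdata)):
        raise ValueError(f"label map has non-integer voxel values: {path}")
    labels = np.round(fdata).astype(np.int32)
    if labels.max() == 0:
        logger.warning("label map %s has no foreground labels", path)

    label_names: dict[int, str] = {}
    sidecar = _sidecar_path(str(path))
    if os.path.exists(sidecar):
        import pandas as pd

        tbl = pd.read_csv(sidecar, sep="\t")
        label_names = dict(zip(tbl.iloc[:, 0].astype(int), tbl.iloc[:, 1].astype(str)))

    zooms = img.header.get_zooms()[:3]
    return LabelMap(
        labels=labels,
        voxel_size_mm=np.asarray(zooms, dtype=float),
        affine=img.affine,
        label_names=label_names,
    )


def write_labelmap(lm: LabelMap, path: str | os.PathLike) -> str:
    """Write a LabelMap as int16 NIfTI plus a TSV name sidecar if names exist."""
    img = nib.Nifti1Image(lm.labels.astype(np.int16), lm.affine)
    img.header.set_zooms(tuple(lm.voxel_size_mm))
    nib.save(img, str(path))
    if lm.label_names:
        import pandas as pd

        pd.DataFrame(
            {"label": list(lm.label_names), "name": list(lm.label_names.values())}
        ).to_csv(_sidecar_path(str(path)), sep="\t", index=False)
    return str(path)


def roi_from_mask(mask: np.ndarray) -> ROIMask:
    """Build an ROIMask with the canonical lexicographic (x, y, z) coords.

    np.argwhere on a C-ordered array already yields lexicographic order; we
    sort explicitly anyway so the contract does not depend on layout.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    coords = np.argwhere(mask)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return ROIMask(mask=mask, coords=coords[order])


def read_roi_mask(path: str | os.PathLike) -> ROIMask:
    """Load a binary NIfTI mask as an ROIMask."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D: {path}")
    return roi_from_mask(data > 0)


def extract_roi_timeseries(vol: Volume4D, roi: ROIMask) -> VoxelTimeSeriesMatrix:
    """Pull the N in-ROI voxel time courses out of a 4D volume.

    Row order equals ``roi.coords`` order.  Zero-variance rows are flagged,
    not removed: the graph module defines their correlations as 0.
    """
    if vol.shape3d != roi.mask.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape3d} vs mask {roi.mask.shape}"
        )
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    ts = vol.data[tuple(roi.coords.T)].astype(float)
    zv = ts.std(axis=1) == 0
    if zv.any():
        logger.warning("%d zero-variance voxel time series in ROI", int(zv.sum()))
    return VoxelTimeSeriesMatrix(ts=ts, coords=roi.coords, tr_s=vol.tr_s, zero_variance=zv)
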