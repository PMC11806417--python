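"""Core imaging containers: volumes, ROI masks, and ROI statistics.

All quantification in this package operates on two objects: a 3-D scalar
:class:`ImageVolume` (intensities on a named acquisition grid, voxel sizes
in mm) and a :class:`RoiMask` (a set of 0-based ``(i, j, k)`` voxel indices
on the same grid).  The third axis (``k``) is the axial slice index,
ordered inferior -> superior.  ROI summary statistics use the unbiased
(n - 1) standard deviation throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "RoiMask",
    "RoiStats",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "roi_stats",
    "average_volumes",
    "rois_from_labelmap",
]


class GridMismatchError(ValueError):
    """Raised when a volume and a mask do not live on the same grid."""


@dataclass
class ImageVolume:
    """A 3-D scalar intensity image with voxel dimensions in mm.

    Parameters
    ----------
    data : ndarray
        3-D float array of intensities (arbitrary units). Must be NaN-free.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` in mm; all strictly positive. ``dz`` is the
        effective slice spacing (slice thickness + interslice gap).
    grid_id : str
        Name of the acquisition grid; masks must carry the same id to be
        used with this volume.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    grid_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or any(s <= 0 for s in self.data.shape):
            raise ValueError(
                f"non-3D volume: expected three positive dimensions, got shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be three positive numbers, got {self.voxel_size}")
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN voxels; refusing to load (intensity thresholds downstream)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.voxel_size, self.grid_id)


@dataclass
class RoiMask:
    """A labelled set of voxel indices on a named grid.

    ``voxels`` is an ``(n, 3)`` int array of 0-based ``(i, j, k)`` indices,
    stored sorted lexicographically so that operations are independent of
    the order in which voxels were supplied.
    """

    label: str
    voxels: np.ndarray
    grid_id: str = ""
    side: str = "none"  # {left, right, bilateral, none}

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.intp)
        if vox.ndim != 2 or vox.shape[1] != 3 or vox.shape[0] == 0:
            raise ValueError(f"ROI '{self.label}' must be a non-empty (n, 3) index array")
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        self.voxels = vox[order]
        if self.side not in {"left", "right", "bilateral", "none"}:
            raise ValueError(f"invalid side {self.side!r}")

    def __len__(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def slices(self) -> np.ndarray:
        """Sorted unique axial slice indices occupied by the ROI."""
        return np.unique(self.voxels[:, 2])

    def index_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2])

    def values(self, volume: ImageVolume) -> np.ndarray:
        """Intensities of this ROI's voxels in ``volume`` (grid-checked)."""
        _check_compatible(volume, self)
        return volume.data[self.index_tuple()]

    def restricted_to_slices(self, slices) -> "RoiMask":
        keep = np.isin(self.voxels[:, 2], np.asarray(list(slices)))
        if not keep.any():
            raise ValueError(f"ROI '{self.label}' has no voxels on slices {list(slices)}")
        return RoiMask(self.label, self.voxels[keep], self.grid_id, self.side)

    def intersects(self, other: "RoiMask") -> bool:
        a = {tuple(v) for v in self.voxels}
        return any(tuple(v) in a for v in other.voxels)


@dataclass(frozen=True)
class RoiStats:
    """Mean and unbiased SD of intensities over an ROI."""

    mean: float
    sd: float
    n_voxels: int


def _grid_id_from_header(img: nib.Nifti1Image) -> str:
    h = hashlib.sha1()
    h.update(np.asarray(img.shape, dtype=np.int64).tobytes())
    h.update(np.round(np.asarray(img.header.get_zooms()[:3], dtype=np.float64), 6).tobytes())
    h.update(np.round(img.affine, 4).tobytes())
    return h.hexdigest()[:12]


def read_volume(path, expected_grid: str | None = None) -> ImageVolume:
    """Read a 3-D NIfTI volume.

    Voxel sizes come from the header zooms; ``grid_id`` is a hash of the
    header geometry unless ``expected_grid`` is given. Non-3D files and
    NaN voxels are rejected.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D volume: {path} has {data.ndim} dimensions")
    if np.isnan(data).any():
        raise ValueError(f"volume {path} contains NaN voxels")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = expected_grid if expected_grid is not None else _grid_id_from_header(img)
    return ImageVolume(np.asarray(data, dtype=np.float64), zooms, grid)


def write_volume(volume: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def _check_compatible(volume: ImageVolume, roi: RoiMask) -> None:
    if roi.grid_id != volume.grid_id:
        raise GridMismatchError(
            f"ROI '{roi.label}' on grid {roi.grid_id!r} used with volume on grid {volume.grid_id!r}"
        )
    if (roi.voxels < 0).any() or (roi.voxels >= np.asarray(volume.shape)).any():
        raise IndexError(f"ROI '{roi.label}' has voxels outside volume shape {volume.shape}")


def roi_stats(volume: ImageVolume, roi: RoiMask) -> RoiStats:
    """Mean and unbiased SD of ``volume`` over the ROI voxels.

    The SD uses the (n - 1) denominator; a single-voxel ROI has SD 0.
    """
    vals = roi.values(volume)
    n = vals.size
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return RoiStats(mean=float(np.mean(vals)), sd=sd, n_voxels=int(n))


def average_volumes(volumes: list[ImageVolume]) -> ImageVolume:
    """Voxel-wise arithmetic mean of already-aligned repeat acquisitions."""
    if not volumes:
        raise ValueError("need at least one volume")
    first = volumes[0]
    for v in volumes[1:]:
        if v.shape != first.shape or v.voxel_size != first.voxel_size or v.grid_id != first.grid_id:
            raise GridMismatchError("volumes to average must share shape, voxel size and grid")
    data = np.mean([v.data for v in volumes], axis=0)
    return ImageVolume(data, first.voxel_size, first.grid_id)


def rois_from_labelmap(labelmap: ImageVolume, mapping: dict) -> dict[str, RoiMask]:
    """Split an integer label map into named ROI masks.

    ``mapping`` maps ROI label (str) to either an integer value or a dict
    ``{"value": int, "side": str}``. Voxels holding each value become one
    :class:`RoiMask` on the label map's grid.
    """
    out: dict[str, RoiMask] = {}
    lab = np.rint(labelmap.data).astype(np.int64)
    for name, entry in mapping.items():
        if isinstance(entry, dict):
            value, side = int(entry["value"]), entry.get("side", "none")
        else:
            value, side = int(entry), "none"
        idx = np.argwhere(lab == value)
        if idx.shape[0] == 0:
            raise ValueError(f"label value {value} for ROI '{name}' not present in label map")
        out[name] = RoiMask(name, idx, labelmap.grid_id, side)
    return out
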