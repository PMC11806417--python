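"""Locus coeruleus neuromelanin contrast per rostro-caudal subdivision.

The LC signal is extracted from a bilateral pair of "search ROIs" on an
averaged, slice-intensity-corrected T1 FSE pons slab.  Each search ROI is
divided along the slice axis into three equal parts (rostral, middle,
caudal); within each part the mean intensity of the five brightest
connected voxels is taken, and the neuromelanin-specific contrast is

    contrast = (mean_LC - mean_background) / mean_background

against a pooled pons background ROI.  Left and right contrasts are
averaged per section.

The slice axis runs inferior -> superior, so the *rostral* section is the
block of highest slice indices and the *caudal* section the lowest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, RoiMask, RoiStats

__all__ = [
    "LcConfig",
    "LcContrasts",
    "slice_intensity_correct",
    "tripartition",
    "brightest_cluster",
    "lc_contrast",
    "lc_summarize",
]

SECTIONS = ("rostral", "middle", "caudal")


@dataclass
class LcConfig:
    """Cluster-extraction settings for the LC search ROIs.

    n_cluster : voxels per cluster (default 5, the "five brightest
        connected voxels").
    connectivity : 3-D neighbourhood order, one of {6, 18, 26}; default 26.
    n_sections : rostro-caudal subdivisions (default 3).
    """

    n_cluster: int = 5
    connectivity: int = 26
    n_sections: int = 3

    def __post_init__(self) -> None:
        if self.n_cluster < 1:
            raise ValueError("n_cluster must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")


@dataclass(frozen=True)
class LcContrasts:
    """Per side x section contrasts plus left/right-averaged sections."""

    per_side: dict  # {(side, section): contrast}
    background_mean: float

    def average(self, section: str) -> float:
        return (self.per_side[("left", section)] + self.per_side[("right", section)]) / 2.0

    @property
    def rostral(self) -> float:
        return self.average("rostral")

    @property
    def middle(self) -> float:
        return self.average("middle")

    @property
    def caudal(self) -> float:
        return self.average("caudal")


def slice_intensity_correct(volume: ImageVolume, reference_roi: RoiMask) -> ImageVolume:
    """Multiplicative slice-to-slice intensity correction.

    Each axial slice that the reference ROI touches is rescaled so its
    reference-ROI mean equals the grand reference mean across those
    slices; slices with no reference voxels are left untouched.  A purely
    multiplicative correction preserves within-slice intensity ratios and
    hence LC contrast.
    """
    if reference_roi.grid_id != volume.grid_id:
        raise ValueError("reference ROI grid mismatch")
    vox = reference_roi.voxels
    vals = volume.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    slices = reference_roi.slices
    slice_means = {int(k): float(np.mean(vals[vox[:, 2] == k])) for k in slices}
    if any(m == 0 for m in slice_means.values()):
        raise ValueError("reference ROI has a zero-mean slice; cannot rescale")
    grand = float(np.mean(list(slice_means.values())))
    out = volume.data.copy()
    for k, m in slice_means.items():
        out[:, :, k] *= grand / m
    return ImageVolume(out, volume.voxel_size, volume.grid_id)


def tripartition(search_roi: RoiMask, n_sections: int = 3) -> list[RoiMask]:
    """Split a search ROI into contiguous rostro-caudal slice blocks.

    The ROI's occupied slices are ordered superior -> inferior and split
    into ``n_sections`` contiguous blocks whose slice counts differ by at
    most one; remainder slices go to the rostral-most blocks first.
    Returns sections rostral-first; their union is the input ROI and they
    are pairwise disjoint.
    """
    slices = search_roi.slices[::-1]  # descending k: rostral (superior) first
    n = slices.size
    if n < n_sections:
        raise ValueError(
            f"ROI '{search_roi.label}' spans {n} slices; need >= {n_sections} for {n_sections} sections"
        )
    base, rem = divmod(n, n_sections)
    sizes = [base + (1 if i < rem else 0) for i in range(n_sections)]
    out, start = [], 0
    names = SECTIONS if n_sections == 3 else [f"section{i}" for i in range(n_sections)]
    for i, size in enumerate(sizes):
        block = slices[start : start + size]
        start += size
        sec = search_roi.restricted_to_slices(block)
        out.append(RoiMask(f"{search_roi.label}_{names[i]}", sec.voxels, sec.grid_id, search_roi.side))
    return out


def _neighbour_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    return np.asarray(offs, dtype=np.intp)


def brightest_cluster(
    volume: ImageVolume, roi: RoiMask, cfg: LcConfig | None = None
) -> tuple[float, np.ndarray]:
    """Greedy extraction of the n brightest connected voxels in an ROI.

    Seeds at the ROI's brightest voxel and repeatedly adds the brightest
    ROI voxel adjacent (by ``cfg.connectivity``) to the current set, until
    ``cfg.n_cluster`` voxels are collected.  Ties are broken by the lowest
    ``(i, j, k)`` index.  Returns the cluster's mean intensity and its
    ``(n, 3)`` voxel array.

    Raises if the ROI is smaller than ``n_cluster`` or if no connected
    component of the ROI holds ``n_cluster`` voxels.
    """
    cfg = cfg or LcConfig()
    vals = roi.values(volume)
    vox = roi.voxels
    n = vox.shape[0]
    if n < cfg.n_cluster:
        raise ValueError(f"ROI '{roi.label}' has {n} voxels < n_cluster={cfg.n_cluster}")
    index_of = {tuple(v): i for i, v in enumerate(vox)}
    offs = _neighbour_offsets(cfg.connectivity)

    # seed: brightest voxel, ties -> lowest (i, j, k); vox is lex-sorted
    seed = int(np.argmax(vals))
    chosen = [seed]
    in_set = np.zeros(n, dtype=bool)
    in_set[seed] = True
    frontier: set[int] = set()

    def add_neighbours(idx: int) -> None:
        base = vox[idx]
        for off in offs:
            j = index_of.get((base[0] + off[0], base[1] + off[1], base[2] + off[2]))
            if j is not None and not in_set[j]:
                frontier.add(j)

    add_neighbours(seed)
    while len(chosen) < cfg.n_cluster:
        if not frontier:
            raise ValueError(
                f"ROI '{roi.label}': connected component of the seed has fewer than "
                f"{cfg.n_cluster} voxels"
            )
        # brightest frontier voxel; ties -> lowest lexicographic index
        best = min(frontier, key=lambda j: (-vals[j], j))
        frontier.discard(best)
        in_set[best] = True
        chosen.append(best)
        add_neighbours(best)
    cluster = vox[np.sort(np.asarray(chosen))]
    return float(np.mean(vals[chosen])), cluster


def lc_contrast(lc_mean: float, bg: RoiStats) -> float:
    """Neuromelanin-specific contrast ``(lc_mean - bg.mean) / bg.mean``."""
    if bg.mean <= 0:
        raise ValueError("background mean must be positive")
    return (lc_mean - bg.mean) / bg.mean


def lc_summarize(per_side: dict, background_mean: float, sections=SECTIONS) -> LcContrasts:
    """Bundle side x section contrasts; checks all cells are present."""
    for side in ("left", "right"):
        for sec in sections:
            if (side, sec) not in per_side:
                raise ValueError(f"missing LC contrast cell ({side}, {sec})")
    return LcContrasts(per_side=dict(per_side), background_mean=float(background_mean))
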