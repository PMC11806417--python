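"""Substantia nigra neuromelanin signal-volume estimation.

The neuromelanin-associated signal in the SN is quantified as the volume of
ROI voxels whose intensity exceeds a background-referenced threshold
``mean + k * SD``, where the mean and SD are measured in a cerebral-peduncle
background ROI on the same averaged MT-GRE image (default ``k = 3.25``).
Exceedance is strict (">"), and the background
statistic is pooled over both peduncles, giving a single threshold per
subject for the four SN subregions (anterior/posterior x left/right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, RoiMask, RoiStats, roi_stats

__all__ = ["SnThresholdConfig", "SnVolumes", "sn_threshold", "sn_signal_volume", "sn_summarize"]

SN_REGIONS = ("asn_left", "asn_right", "psn_left", "psn_right")


@dataclass
class SnThresholdConfig:
    """Background-referenced threshold rule for SN hyperintensity.

    k : SD multiplier (dimensionless), default 3.25.
    strict : exceedance is strict ``>`` (default) rather than ``>=``.
    voxel_volume_mm3 : mm^3 per voxel; ``None`` means take it from the
        image header at use time.
    """

    k: float = 3.25
    strict: bool = True
    voxel_volume_mm3: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.voxel_volume_mm3 is not None and self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be > 0")


@dataclass(frozen=True)
class SnVolumes:
    """Per-region SN neuromelanin signal volumes in mm^3.

    ``avg_asn``/``avg_psn`` are left/right means, ``avg_sn`` the mean of
    all four regions, and ``total_sn = avg_asn + avg_psn`` the combined
    anterior + posterior average volume.
    """

    asn_left: float
    asn_right: float
    psn_left: float
    psn_right: float

    @property
    def avg_asn(self) -> float:
        return (self.asn_left + self.asn_right) / 2.0

    @property
    def avg_psn(self) -> float:
        return (self.psn_left + self.psn_right) / 2.0

    @property
    def avg_sn(self) -> float:
        return (self.asn_left + self.asn_right + self.psn_left + self.psn_right) / 4.0

    @property
    def total_sn(self) -> float:
        return self.avg_asn + self.avg_psn


def sn_threshold(bg: RoiStats, cfg: SnThresholdConfig | None = None) -> float:
    """Intensity threshold ``bg.mean + k * bg.sd``."""
    cfg = cfg or SnThresholdConfig()
    if bg.sd < 0:
        raise ValueError("background SD must be >= 0")
    return bg.mean + cfg.k * bg.sd


def sn_signal_volume(
    volume: ImageVolume,
    sn_roi: RoiMask,
    bg_roi: RoiMask,
    cfg: SnThresholdConfig | None = None,
) -> float:
    """Volume (mm^3) of SN-ROI voxels exceeding the background threshold.

    The SN ROI and the background ROI must be disjoint and share the
    volume's grid. Deterministic: a pure per-voxel comparison.
    """
    cfg = cfg or SnThresholdConfig()
    if sn_roi.intersects(bg_roi):
        raise ValueError(f"SN ROI '{sn_roi.label}' overlaps background ROI '{bg_roi.label}'")
    bg = roi_stats(volume, bg_roi)
    thr = sn_threshold(bg, cfg)
    vals = sn_roi.values(volume)
    n_exceed = int(np.sum(vals > thr)) if cfg.strict else int(np.sum(vals >= thr))
    vv = cfg.voxel_volume_mm3 if cfg.voxel_volume_mm3 is not None else volume.voxel_volume_mm3
    return n_exceed * vv


def sn_summarize(per_region: dict[str, float]) -> SnVolumes:
    """Bundle the four regional volumes and their averages.

    ``per_region`` must contain mm^3 values for all of
    ``asn_left, asn_right, psn_left, psn_right``.
    """
    missing = [r for r in SN_REGIONS if r not in per_region]
    if missing:
        raise ValueError(f"missing SN regions: {missing}")
    return SnVolumes(*(float(per_region[r]) for r in SN_REGIONS))
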