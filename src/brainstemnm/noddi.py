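"""ROI summaries of NODDI parameter maps (NDI, ODI, FWF).

The NODDI model fit itself is upstream; this module takes the three fitted
parameter maps as inputs and extracts arithmetic ROI means over small
(default 8-voxel) anterior/posterior SN ROIs per side, plus left/right
side averages.  All three parameters are fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, RoiMask

__all__ = ["NoddiMaps", "NoddiRoiSummary", "extract_noddi"]

METRICS = ("ndi", "odi", "fwf")
REGIONS = ("asn", "psn")


@dataclass
class NoddiMaps:
    """The three NODDI parameter maps on one grid."""

    ndi: ImageVolume
    odi: ImageVolume
    fwf: ImageVolume

    def __post_init__(self) -> None:
        ref = self.ndi
        for name in ("odi", "fwf"):
            m = getattr(self, name)
            if m.shape != ref.shape or m.grid_id != ref.grid_id:
                raise ValueError(f"{name} map does not share the NDI map's shape/grid")

    def __getitem__(self, metric: str) -> ImageVolume:
        return getattr(self, metric)


@dataclass(frozen=True)
class NoddiRoiSummary:
    """Regional and side-averaged NODDI means.

    ``regional`` maps ``(region, side, metric)`` -> mean;
    ``side_avg`` maps ``(region, metric)`` -> left/right mean.
    """

    regional: dict
    side_avg: dict


def extract_noddi(
    maps: NoddiMaps,
    rois: list[RoiMask],
    expected_voxels: int = 8,
    on_size_mismatch: str = "fail",
) -> NoddiRoiSummary:
    """Arithmetic ROI means of NDI/ODI/FWF with side averaging.

    ``rois`` must contain masks labelled ``asn``/``psn`` with sides
    ``left``/``right`` (four masks).  Each ROI is expected to hold
    ``expected_voxels`` voxels; a mismatch raises (``on_size_mismatch=
    "fail"``) or is tolerated (``"warn"``).  Any map value outside
    [0, 1] inside an ROI is an error.
    """
    if on_size_mismatch not in ("fail", "warn"):
        raise ValueError("on_size_mismatch must be 'fail' or 'warn'")
    by_key = {}
    for roi in rois:
        region = roi.label.lower()
        if region not in REGIONS:
            raise ValueError(f"unexpected NODDI ROI label {roi.label!r}; want one of {REGIONS}")
        if len(roi) != expected_voxels:
            msg = f"ROI {roi.label}/{roi.side} has {len(roi)} voxels, expected {expected_voxels}"
            if on_size_mismatch == "fail":
                raise ValueError(msg)
            import warnings

            warnings.warn(msg)
        by_key[(region, roi.side)] = roi

    for region in REGIONS:
        for side in ("left", "right"):
            if (region, side) not in by_key:
                raise ValueError(f"missing NODDI ROI ({region}, {side})")

    regional = {}
    for (region, side), roi in by_key.items():
        for metric in METRICS:
            vals = roi.values(maps[metric])
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{metric} values outside [0, 1] in ROI {region}/{side}")
            regional[(region, side, metric)] = float(np.mean(vals))
    side_avg = {
        (region, metric): (regional[(region, "left", metric)] + regional[(region, "right", metric)]) / 2.0
        for region in REGIONS
        for metric in METRICS
    }
    return NoddiRoiSummary(regional=regional, side_avg=side_avg)
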