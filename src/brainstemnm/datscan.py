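"""DAT-SPECT specific binding ratios and normative Z-scores.

The specific binding ratio (SBR) for a striatal ROI is

    SBR = (ROI count density - occipital count density) / occipital count density

and the normative Z-score expresses the deviation of the observed SBR from
the SBR expected for the subject's age and sex under a linear normative
model, in residual-SD units:

    Z = (SBR - (intercept + slope * age)) / residual_sd

A scan is flagged abnormal when Z is strictly below -2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormativeEntry", "NormativeModel", "DatResult", "sbr", "dat_z", "dat_table", "most_affected_putamen"]

DAT_ROIS = ("caudate", "putamen", "striatum")
SIDES = ("left", "right")


@dataclass(frozen=True)
class NormativeEntry:
    intercept: float
    age_slope: float  # SBR per year
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be > 0")

    def expected(self, age: float) -> float:
        return self.intercept + self.age_slope * age


@dataclass
class NormativeModel:
    """Sex-stratified, linear-in-age normative SBR model per ROI."""

    entries: dict  # {(roi, sex): NormativeEntry}

    def entry(self, roi: str, sex: str) -> NormativeEntry:
        key = (roi, sex)
        if key not in self.entries:
            raise KeyError(f"no normative entry for ROI {roi!r}, sex {sex!r}")
        return self.entries[key]

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        entries = {}
        for roi, by_sex in d.items():
            for sex, params in by_sex.items():
                entries[(roi, sex)] = NormativeEntry(
                    float(params["intercept"]), float(params["age_slope"]), float(params["residual_sd"])
                )
        return cls(entries)

    def to_dict(self) -> dict:
        out: dict = {}
        for (roi, sex), e in self.entries.items():
            out.setdefault(roi, {})[sex] = {
                "intercept": e.intercept,
                "age_slope": e.age_slope,
                "residual_sd": e.residual_sd,
            }
        return out


@dataclass(frozen=True)
class DatResult:
    sbr: float
    z: float
    abnormal: bool


def sbr(roi_density: float, occipital_density: float) -> float:
    """Specific binding ratio ``(roi - occipital) / occipital``."""
    if occipital_density <= 0:
        raise ValueError("occipital count density must be positive")
    return (roi_density - occipital_density) / occipital_density


def dat_z(sbr_value: float, age: float, sex: str, model: NormativeModel, roi: str) -> DatResult:
    """Normative Z for an observed SBR; abnormal iff Z < -2 (strict)."""
    e = model.entry(roi, sex)
    z = (sbr_value - e.expected(age)) / e.residual_sd
    return DatResult(sbr=float(sbr_value), z=float(z), abnormal=bool(z < -2.0))


def dat_table(counts: pd.DataFrame, cohort: pd.DataFrame, model: NormativeModel) -> pd.DataFrame:
    """Compute SBR/Z/abnormal columns for a table of count densities.

    ``counts`` must have columns ``subject_id``, ``occipital`` and
    ``{roi}_{side}`` for the six striatal ROIs; ``cohort`` supplies
    ``subject_id``, ``age``, ``sex``.  Subjects missing from ``counts``
    get all-NaN DAT columns (missingness propagates).
    """
    merged = cohort[["subject_id", "age", "sex"]].merge(counts, on="subject_id", how="left")
    rows = []
    for _, r in merged.iterrows():
        row = {"subject_id": r["subject_id"]}
        has_dat = pd.notna(r.get("occipital", np.nan))
        for roi in DAT_ROIS:
            for side in SIDES:
                col = f"{roi}_{side}"
                if has_dat and pd.notna(r.get(col, np.nan)):
                    s = sbr(float(r[col]), float(r["occipital"]))
                    res = dat_z(s, float(r["age"]), str(r["sex"]), model, roi)
                    row[f"sbr_{col}"] = res.sbr
                    row[f"z_{col}"] = res.z
                    row[f"abnormal_{col}"] = res.abnormal
                else:
                    row[f"sbr_{col}"] = np.nan
                    row[f"z_{col}"] = np.nan
                    row[f"abnormal_{col}"] = np.nan
        if has_dat:
            row["z_putamen_most_affected"] = most_affected_putamen(row)
        else:
            row["z_putamen_most_affected"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def most_affected_putamen(row: dict) -> float:
    """Z of the putamen with the lower Z-score; ties resolve to the left."""
    zl, zr = row.get("z_putamen_left", np.nan), row.get("z_putamen_right", np.nan)
    if pd.isna(zl) and pd.isna(zr):
        return np.nan
    if pd.isna(zr) or (pd.notna(zl) and zl <= zr):
        return float(zl)
    return float(zr)
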