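"""End-to-end orchestration: quantification -> statistics -> reports.

``quantify_subject`` turns one subject's rendered (or loaded) volumes and
masks into a flat row of derived measures; ``run_quantify`` does this for
a simulated dataset directory; ``run_stats`` produces the three report
tables (group-comparison table, correlation family, w-scores).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImageVolume, RoiMask, read_volume, roi_stats, rois_from_labelmap
from .datscan import NormativeModel, dat_table
from .lc import LcConfig, brightest_cluster, lc_contrast, lc_summarize, slice_intensity_correct, tripartition
from .noddi import NoddiMaps, extract_noddi
from .sn import SnThresholdConfig, sn_signal_volume, sn_summarize, SN_REGIONS
from .stats import GlmSpec, PermutationAncova, correlation_family, levene
from .synthetic import LC_LABEL_MAP, NODDI_LABEL_MAP, SN_LABEL_MAP
from .wscore import DEFAULT_WSCORE_OUTCOMES, ControlNormative

__all__ = [
    "TABLE_OUTCOMES",
    "DEFAULT_CORRELATION_PAIRS",
    "quantify_subject",
    "run_quantify",
    "run_stats",
]

# the 11 group-comparison outcomes (6 NODDI, 2 SN neuromelanin, 3 LC)
TABLE_OUTCOMES = (
    "ndi_asn_avg",
    "ndi_psn_avg",
    "fwf_asn_avg",
    "fwf_psn_avg",
    "odi_asn_avg",
    "odi_psn_avg",
    "nm_asn_avg",
    "nm_psn_avg",
    "lc_rostral_avg",
    "lc_middle_avg",
    "lc_caudal_avg",
)

# combined iRBD+PD correlation family over SN-averaged measures and motor score
DEFAULT_CORRELATION_PAIRS = (
    ("nm_sn_avg", "ndi_sn_avg"),
    ("nm_sn_avg", "odi_sn_avg"),
    ("nm_sn_avg", "fwf_sn_avg"),
    ("ndi_sn_avg", "fwf_sn_avg"),
    ("ndi_sn_avg", "odi_sn_avg"),
    ("updrs3", "nm_sn_avg"),
    ("updrs3", "ndi_sn_avg"),
    ("updrs3", "odi_sn_avg"),
    ("updrs3", "fwf_sn_avg"),
)


def quantify_subject(
    sn_image: ImageVolume,
    sn_rois: dict,
    lc_image: ImageVolume,
    lc_rois: dict,
    noddi_maps: NoddiMaps,
    noddi_rois: list,
    sn_cfg: SnThresholdConfig | None = None,
    lc_cfg: LcConfig | None = None,
) -> dict:
    """All derived measures for one subject as a flat dict of columns."""
    sn_cfg = sn_cfg or SnThresholdConfig()
    lc_cfg = lc_cfg or LcConfig()
    row: dict = {}

    # SN neuromelanin signal volume (pooled peduncle background)
    per_region = {
        r: sn_signal_volume(sn_image, sn_rois[r], sn_rois["peduncle"], sn_cfg) for r in SN_REGIONS
    }
    vols = sn_summarize(per_region)
    for r in SN_REGIONS:
        row[f"nm_{r}"] = per_region[r]
    row["nm_asn_avg"] = vols.avg_asn
    row["nm_psn_avg"] = vols.avg_psn
    row["nm_sn_avg"] = vols.avg_sn
    row["nm_sn_total"] = vols.total_sn

    # LC contrast per rostro-caudal section (slice-corrected, pooled pons bg)
    corrected = slice_intensity_correct(lc_image, lc_rois["pons"])
    bg = roi_stats(corrected, lc_rois["pons"])
    per_side = {}
    for side in ("left", "right"):
        sections = tripartition(lc_rois[f"lc_{side}"], lc_cfg.n_sections)
        for name, sec in zip(("rostral", "middle", "caudal"), sections):
            mean, _ = brightest_cluster(corrected, sec, lc_cfg)
            per_side[(side, name)] = lc_contrast(mean, bg)
    contrasts = lc_summarize(per_side, bg.mean)
    for side in ("left", "right"):
        for sec in ("rostral", "middle", "caudal"):
            row[f"lc_{sec}_{side}"] = per_side[(side, sec)]
    for sec in ("rostral", "middle", "caudal"):
        row[f"lc_{sec}_avg"] = contrasts.average(sec)

    # NODDI ROI means
    summary = extract_noddi(noddi_maps, noddi_rois)
    for (region, side, metric), v in summary.regional.items():
        row[f"{metric}_{region}_{side}"] = v
    for (region, metric), v in summary.side_avg.items():
        row[f"{metric}_{region}_avg"] = v
    for metric in ("ndi", "odi", "fwf"):
        row[f"{metric}_sn_avg"] = (row[f"{metric}_asn_avg"] + row[f"{metric}_psn_avg"]) / 2.0
    return row


def _sided(mapping_flat: dict) -> dict:
    out = {}
    for name, value in mapping_flat.items():
        side = "none"
        for s in ("left", "right"):
            if name.endswith(s):
                side = s
        if name in ("peduncle", "pons"):
            side = "bilateral"
        out[name] = {"value": value, "side": side}
    return out


def run_quantify(
    data_dir,
    cohort: pd.DataFrame,
    dat_counts: pd.DataFrame | None = None,
    normative: NormativeModel | None = None,
    sn_cfg: SnThresholdConfig | None = None,
    lc_cfg: LcConfig | None = None,
    log=print,
) -> pd.DataFrame:
    """Quantify every subject under ``data_dir`` (one directory each).

    Missing DAT rows propagate as NaN columns.  Returns one row per
    subject joined with the cohort table.
    """
    data_dir = Path(data_dir)
    rows = []
    for _, subj in cohort.iterrows():
        sid = str(subj["subject_id"])
        sdir = data_dir / sid
        try:
            sn_img = read_volume(sdir / "sn.nii.gz", expected_grid="sn")
            sn_rois = rois_from_labelmap(read_volume(sdir / "sn_labels.nii.gz", "sn"), _sided(SN_LABEL_MAP))
            lc_img = read_volume(sdir / "lc.nii.gz", expected_grid="lc")
            lc_rois = rois_from_labelmap(read_volume(sdir / "lc_labels.nii.gz", "lc"), _sided(LC_LABEL_MAP))
            maps = NoddiMaps(
                ndi=read_volume(sdir / "ndi.nii.gz", "noddi"),
                odi=read_volume(sdir / "odi.nii.gz", "noddi"),
                fwf=read_volume(sdir / "fwf.nii.gz", "noddi"),
            )
            lab = read_volume(sdir / "noddi_labels.nii.gz", "noddi")
            noddi_flat = {f"{region}_{side}": v for (region, side), v in NODDI_LABEL_MAP.items()}
            named = rois_from_labelmap(lab, _sided(noddi_flat))
            noddi_rois = [
                RoiMask(name.split("_")[0], roi.voxels, roi.grid_id, roi.side)
                for name, roi in named.items()
            ]
            row = quantify_subject(sn_img, sn_rois, lc_img, lc_rois, maps, noddi_rois, sn_cfg, lc_cfg)
        except Exception as exc:
            raise RuntimeError(f"quantification failed for subject {sid}: {exc}") from exc
        row["subject_id"] = sid
        rows.append(row)
    results = cohort.merge(pd.DataFrame(rows), on="subject_id", how="left", suffixes=("_cohort", ""))
    if dat_counts is not None:
        from .synthetic import default_normative_model

        dat = dat_table(dat_counts, cohort, normative or default_normative_model())
        results = results.merge(dat, on="subject_id", how="left")
        n_missing = int(results["z_putamen_most_affected"].isna().sum())
        log(f"DAT: {len(results) - n_missing} subjects scanned, {n_missing} without DAT data")
    log(f"quantified {len(results)} subjects")
    return results


def run_stats(
    results: pd.DataFrame,
    outcomes=TABLE_OUTCOMES,
    correlation_pairs=DEFAULT_CORRELATION_PAIRS,
    wscore_outcomes: dict | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    log=print,
) -> dict:
    """Group-comparison, correlation and w-score reports.

    Returns ``{"table": DataFrame, "correlations": DataFrame,
    "wscores": DataFrame}``.  Statistical preconditions that fail for one
    outcome are logged and skipped, not fatal.
    """
    table_rows = []
    for i, outcome in enumerate(outcomes):
        try:
            spec = GlmSpec(outcome=outcome, n_perm=n_perm, seed=seed + i)
            res = PermutationAncova(results, spec).fit()
            W, p_lev = levene(results, outcome)
            row = {
                "outcome": outcome,
                "F": res.omnibus.F,
                "df_between": res.omnibus.df[0],
                "df_resid": res.omnibus.df[1],
                "p_param": res.omnibus.p_param,
                "p_perm": res.omnibus.p_perm,
                "levene_W": W,
                "levene_p": p_lev,
                "n": res.omnibus.n_used,
            }
            for g, sub in results.groupby("group", observed=True):
                row[f"mean_{g}"] = float(sub[outcome].mean())
                row[f"sd_{g}"] = float(sub[outcome].std(ddof=1))
            for c in res.contrasts:
                key = c.label.replace(" > ", "_gt_")
                row[f"T_{key}"] = c.T
                row[f"p_perm_{key}"] = c.p_perm
                row[f"p_fwer_{key}"] = c.p_fwer
            table_rows.append(row)
        except Exception as exc:
            log(f"stats skipped for outcome {outcome}: {exc}")
    table = pd.DataFrame(table_rows)

    results = results.copy()
    # SN-level averages used by the correlation family, derived on the fly
    # when the input table only carries the regional averages
    for metric in ("nm", "ndi", "odi", "fwf"):
        col = f"{metric}_sn_avg"
        parts = [f"{metric}_asn_avg", f"{metric}_psn_avg"]
        if col not in results.columns and all(p in results.columns for p in parts):
            results[col] = (results[parts[0]] + results[parts[1]]) / 2.0

    patients = results["group"].isin(["iRBD", "PD"])
    pairs = [p for p in correlation_pairs if all(c in results.columns for c in p)]
    try:
        correlations = correlation_family(results, pairs, subset=patients)
    except Exception as exc:
        log(f"correlation family failed: {exc}")
        correlations = pd.DataFrame()

    wscore_outcomes = wscore_outcomes or DEFAULT_WSCORE_OUTCOMES
    wrows = []
    for outcome, direction in wscore_outcomes.items():
        if outcome not in results.columns:
            log(f"w-score outcome {outcome} not in results; skipped")
            continue
        try:
            norm = ControlNormative.from_dataframe(results, outcome).fit()
            frame = norm.wscore_frame(results[patients], direction=direction)
            wrows.append(frame)
        except Exception as exc:
            log(f"w-score failed for {outcome}: {exc}")
    wscores = pd.concat(wrows, ignore_index=True) if wrows else pd.DataFrame()
    if not wscores.empty and "z_putamen_most_affected" in results.columns:
        flags = results[["subject_id"]].copy()
        z = results["z_putamen_most_affected"]
        flags["dat_abnormal"] = (z < -2).astype("boolean").mask(z.isna())
        wscores = wscores.merge(flags, on="subject_id", how="left")
    log(
        f"stats: {len(table)} outcomes, {len(correlations)} correlation pairs, "
        f"{0 if wscores.empty else wscores['outcome'].nunique()} w-score outcomes "
        f"(n_perm={n_perm}, seed={seed})"
    )
    return {"table": table, "correlations": correlations, "wscores": wscores}
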