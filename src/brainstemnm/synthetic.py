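"""Synthetic cohorts, brainstem image volumes, NODDI maps and DAT tables.

The generator emulates the data the quantification pipeline consumes, with
known ground truth at every stage:

* a three-group cohort (HC / iRBD / PD) whose per-outcome means and SDs
  default to the published control/patient calibration values, with the
  cross-measure correlation structure placed on subject-level latent
  factors (anterior and posterior subregions of one metric share a
  factor; the matrix is nearest-PSD repaired if needed);
* an MT-GRE-like midbrain slab with a cerebral-peduncle background and
  hyperintense SN voxels planted to match each subject's true
  neuromelanin volume;
* an FSE-like pons slab with 5-voxel connected LC clusters planted per
  rostro-caudal section at the subject's true contrast, plus a per-slice
  multiplicative gain perturbation for the slice-correction step to
  remove;
* NODDI parameter maps with region-true values plus voxel noise, clipped
  to [0, 1];
* a DAT-SPECT count-density table built so the resulting SBR/Z match the
  drawn true values, with a configurable number of planted-abnormal iRBD
  subjects.

Everything is deterministic given the seed; images are drawn from
per-subject child seeds so cohorts of any size reproduce exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import ImageVolume, RoiMask
from .datscan import NormativeModel
from .noddi import NoddiMaps

__all__ = [
    "CohortSpec",
    "ImageSpec",
    "OUTCOME_COLUMNS",
    "generate_cohort",
    "render_subject_images",
    "render_images",
    "generate_dat",
    "default_normative_model",
    "nearest_psd",
]

OUTCOME_COLUMNS = (
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

# group -> outcome -> (mean, sd); the published cohort calibration.
DEFAULT_OUTCOME_PARAMS = {
    "HC": {
        "ndi_asn_avg": (0.811, 0.084),
        "ndi_psn_avg": (0.728, 0.089),
        "fwf_asn_avg": (0.0837, 0.0660),
        "fwf_psn_avg": (0.0680, 0.0631),
        "odi_asn_avg": (0.261, 0.044),
        "odi_psn_avg": (0.259, 0.047),
        "nm_asn_avg": (83.03, 31.11),
        "nm_psn_avg": (28.87, 12.42),
        "lc_rostral_avg": (0.0751, 0.0331),
        "lc_middle_avg": (0.0873, 0.0273),
        "lc_caudal_avg": (0.0331, 0.0368),
    },
    "iRBD": {
        "ndi_asn_avg": (0.841, 0.081),
        "ndi_psn_avg": (0.734, 0.100),
        "fwf_asn_avg": (0.0707, 0.0340),
        "fwf_psn_avg": (0.1022, 0.0796),
        "odi_asn_avg": (0.259, 0.044),
        "odi_psn_avg": (0.254, 0.039),
        "nm_asn_avg": (74.83, 28.93),
        "nm_psn_avg": (25.41, 7.50),
        "lc_rostral_avg": (0.0534, 0.0398),
        "lc_middle_avg": (0.0514, 0.0362),
        "lc_caudal_avg": (-0.0051, 0.0513),
    },
    "PD": {
        "ndi_asn_avg": (0.827, 0.061),
        "ndi_psn_avg": (0.774, 0.104),
        "fwf_asn_avg": (0.072, 0.0592),
        "fwf_psn_avg": (0.1299, 0.1075),
        "odi_asn_avg": (0.277, 0.037),
        "odi_psn_avg": (0.273, 0.029),
        "nm_asn_avg": (61.89, 33.81),
        "nm_psn_avg": (15.85, 13.14),
        "lc_rostral_avg": (0.0611, 0.0423),
        "lc_middle_avg": (0.0540, 0.0446),
        "lc_caudal_avg": (-0.0012, 0.0459),
    },
}

# group -> (mean, sd) clinical calibration; None = not collected in that group.
DEFAULT_CLINICAL_PARAMS = {
    "age": {"HC": (63.1, 11.0), "iRBD": (65.1, 7.9), "PD": (63.1, 9.0)},
    "moca": {"HC": None, "iRBD": (25.9, 3.0), "PD": (27.3, 2.2)},
    "rbdsq": {"HC": (1.5, 1.4), "iRBD": (9.7, 1.8), "PD": (5.2, 3.9)},
    "updrs1": {"HC": None, "iRBD": (7.7, 4.9), "PD": (9.8, 6.1)},
    "updrs2": {"HC": None, "iRBD": (2.0, 2.1), "PD": (8.4, 5.9)},
    "updrs3": {"HC": None, "iRBD": (7.4, 5.9), "PD": (34.1, 14.6)},
}

DEFAULT_SEX_COUNTS = {"HC": (7, 11), "iRBD": (10, 4), "PD": (11, 7)}  # (M, F)

# latent metric factors and the default cross-measure correlations
LATENTS = ("nm", "ndi", "fwf", "odi", "updrs3", "lc_rostral", "lc_middle", "lc_caudal")
DEFAULT_LATENT_CORR = {
    ("nm", "ndi"): -0.610,
    ("ndi", "fwf"): 0.417,
    ("ndi", "odi"): 0.494,
    ("nm", "updrs3"): -0.404,
    ("fwf", "updrs3"): 0.486,
}

_OUTCOME_LATENT = {
    "nm_asn_avg": "nm",
    "nm_psn_avg": "nm",
    "ndi_asn_avg": "ndi",
    "ndi_psn_avg": "ndi",
    "fwf_asn_avg": "fwf",
    "fwf_psn_avg": "fwf",
    "odi_asn_avg": "odi",
    "odi_psn_avg": "odi",
    "lc_rostral_avg": "lc_rostral",
    "lc_middle_avg": "lc_middle",
    "lc_caudal_avg": "lc_caudal",
}


_PSD_WARNED: set = set()


def nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)
    and restore a unit diagonal."""
    w, V = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= eps:
        return corr
    key = np.round(corr, 6).tobytes()
    if key not in _PSD_WARNED:  # warn once per distinct matrix
        _PSD_WARNED.add(key)
        import warnings

        warnings.warn("correlation matrix not PSD; repaired by eigenvalue clipping")
    fixed = (V * np.clip(w, eps, None)) @ V.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


@dataclass
class CohortSpec:
    """Population parameters of the synthetic cohort."""

    group_sizes: dict = field(default_factory=lambda: {"HC": 18, "iRBD": 14, "PD": 18})
    sex_counts: dict = field(default_factory=lambda: dict(DEFAULT_SEX_COUNTS))
    outcome_params: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_OUTCOME_PARAMS.items()})
    clinical_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_PARAMS.items()})
    latent_corr: dict = field(default_factory=lambda: dict(DEFAULT_LATENT_CORR))
    age_range: tuple = (45.0, 80.0)
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(LATENTS)
        C = np.eye(k)
        idx = {name: i for i, name in enumerate(LATENTS)}
        for (a, b), r in self.latent_corr.items():
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
        return nearest_psd(C)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_BOUNDS = {
    "ndi": (0.0, 1.0),
    "odi": (0.0, 1.0),
    "fwf": (0.0, 1.0),
    "nm": (0.0, np.inf),
    "lc": (-0.999, np.inf),
}


def _outcome_bounds(col: str) -> tuple[float, float]:
    return _BOUNDS[col.split("_")[0]]


def generate_cohort(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and its ground truth.

    Outcome vectors are multivariate normal on the latent factors, scaled
    to each group's means/SDs; draws violating the physical bounds
    (volumes >= 0, NODDI fractions in [0, 1], contrasts > -1) are redrawn
    whole-subject, which keeps the correlation structure within the
    accepted region.  Returns ``(cohort, truth)``: ``cohort`` holds
    demographics, clinical scores and the true outcome values; ``truth``
    additionally expands the per-region/side true values the image
    renderer plants.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    C = spec.correlation_matrix()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    rows = []
    sid = 0
    for group in ("HC", "iRBD", "PD"):
        n = spec.group_sizes.get(group, 0)
        m_count, f_count = spec.sex_counts[group]
        if m_count + f_count != n:
            raise ValueError(f"sex counts for {group} must sum to group size {n}")
        sexes = ["M"] * m_count + ["F"] * f_count
        age_mean, age_sd = spec.clinical_params["age"][group]
        ages = _truncated_normal(rng, age_mean, age_sd, *spec.age_range, size=n)
        params = spec.outcome_params[group]
        for i in range(n):
            for _try in range(1000):
                z = L @ rng.standard_normal(len(LATENTS))
                lat = dict(zip(LATENTS, z))
                vals = {}
                ok = True
                for col in OUTCOME_COLUMNS:
                    mean, sd = params[col]
                    v = mean + sd * lat[_OUTCOME_LATENT[col]]
                    lo, hi = _outcome_bounds(col)
                    if not (lo <= v <= hi):
                        ok = False
                        break
                    vals[col] = v
                if ok:
                    break
            else:  # pragma: no cover
                raise RuntimeError(f"could not draw in-bounds outcomes for group {group}")
            sid += 1
            row = {"subject_id": f"S{sid:03d}", "group": group, "age": float(ages[i]), "sex": sexes[i]}
            row.update(vals)
            for score in ("moca", "rbdsq", "updrs1", "updrs2", "updrs3"):
                p = spec.clinical_params[score][group]
                if p is None:
                    row[score] = np.nan
                elif score == "updrs3":
                    mean, sd = p
                    v = mean + sd * lat["updrs3"]
                    while v < 0:
                        v = mean + sd * rng.standard_normal()
                    row[score] = round(float(v))
                else:
                    mean, sd = p
                    hi = 30.0 if score == "moca" else np.inf
                    v = float(_truncated_normal(rng, mean, sd, 0.0, hi, size=1)[0])
                    row[score] = round(v)
            rows.append(row)
    cohort = pd.DataFrame(rows)

    truth = cohort.copy()
    for region in ("asn", "psn"):
        for side in ("left", "right"):
            truth[f"nm_{region}_{side}"] = truth[f"nm_{region}_avg"]
            for metric in ("ndi", "odi", "fwf"):
                truth[f"{metric}_{region}_{side}"] = truth[f"{metric}_{region}_avg"]
    for sec in ("rostral", "middle", "caudal"):
        for side in ("left", "right"):
            truth[f"lc_{sec}_{side}"] = truth[f"lc_{sec}_avg"]
    return cohort, truth


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class ImageSpec:
    """Geometry and noise of the rendered brainstem volumes.

    The MT-GRE-like SN slab and the FSE-like pons slab are 13 axial
    slices of 2.8 mm effective spacing (2.5 mm thickness + 0.3 mm gap)
    with ~0.43 mm in-plane voxels; NODDI maps use 2.2 mm isotropic
    voxels.  ``sn_excess_k`` sets the planted hyperintensity in units of
    the background noise SD.
    """

    sn_shape: tuple = (64, 64, 13)
    sn_voxel: tuple = (0.4297, 0.4297, 2.8)
    sn_bg_mean: float = 100.0
    sn_bg_sd: float = 5.0
    sn_excess_k: float = 10.0
    lc_shape: tuple = (64, 64, 13)
    lc_voxel: tuple = (0.4297, 0.4297, 2.8)
    lc_bg_mean: float = 100.0
    lc_bg_sd: float = 0.5
    lc_search_offset: float = 0.97
    lc_slice_gain_sd: float = 0.02
    noddi_shape: tuple = (48, 48, 13)
    noddi_voxel: tuple = (2.2, 2.2, 2.2)
    noddi_noise_sd: float = 0.02
    noddi_background: float = 0.3


def _block(i0, i1, j0, j1, k0, k1) -> np.ndarray:
    ii, jj, kk = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), np.arange(k0, k1), indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])


# SN slab layout (slices 5..7): four SN drawing regions + bilateral peduncle
_SN_BLOCKS = {
    "asn_left": (4, 18, 8, 18, 5, 8),
    "psn_left": (4, 18, 22, 32, 5, 8),
    "asn_right": (46, 60, 8, 18, 5, 8),
    "psn_right": (46, 60, 22, 32, 5, 8),
}
_PEDUNCLE_BLOCKS = [(4, 18, 38, 48, 5, 8), (46, 60, 38, 48, 5, 8)]

# LC slab layout: search ROIs span slices 2..10 (9 slices), pons background central
_LC_BLOCKS = {"left": (16, 21, 28, 34, 2, 11), "right": (43, 48, 28, 34, 2, 11)}
_PONS_BLOCK = (26, 38, 26, 38, 2, 11)
_LC_CLUSTER_CENTRES = {"left": (18, 30), "right": (45, 30)}
# rostral = superior (high k); cluster planted on each section's middle slice
_LC_SECTION_SLICES = {"rostral": (8, 9, 10), "middle": (5, 6, 7), "caudal": (2, 3, 4)}

_NODDI_BLOCKS = {
    ("asn", "left"): (10, 12, 10, 12, 6, 8),
    ("psn", "left"): (10, 12, 16, 18, 6, 8),
    ("asn", "right"): (30, 32, 10, 12, 6, 8),
    ("psn", "right"): (30, 32, 16, 18, 6, 8),
}


def sn_roi_masks(grid_id: str = "sn") -> dict[str, RoiMask]:
    rois = {
        name: RoiMask(name, _block(*blk), grid_id, side=name.split("_")[1])
        for name, blk in _SN_BLOCKS.items()
    }
    ped = np.vstack([_block(*b) for b in _PEDUNCLE_BLOCKS])
    rois["peduncle"] = RoiMask("peduncle", ped, grid_id, side="bilateral")
    return rois


def lc_roi_masks(grid_id: str = "lc") -> dict[str, RoiMask]:
    rois = {
        f"lc_{side}": RoiMask(f"lc_{side}", _block(*blk), grid_id, side=side)
        for side, blk in _LC_BLOCKS.items()
    }
    rois["pons"] = RoiMask("pons", _block(*_PONS_BLOCK), grid_id, side="bilateral")
    return rois


def noddi_roi_masks(grid_id: str = "noddi") -> list[RoiMask]:
    return [
        RoiMask(region, _block(*blk), grid_id, side=side)
        for (region, side), blk in _NODDI_BLOCKS.items()
    ]


def _plus_cluster(ci: int, cj: int, k: int) -> np.ndarray:
    return np.array([(ci, cj, k), (ci - 1, cj, k), (ci + 1, cj, k), (ci, cj - 1, k), (ci, cj + 1, k)])


def render_subject_images(truth_row: pd.Series | dict, spec: ImageSpec, rng: np.random.Generator) -> dict:
    """Render one subject's volumes and masks from their true values.

    Returns a dict with the SN slab + ROIs, the LC slab + ROIs, the NODDI
    maps + ROIs, and ``planted``: the truth actually realized (SN volumes
    quantized to whole voxels; LC contrasts and NODDI means as drawn).
    """
    t = dict(truth_row)
    planted: dict = {}

    # --- SN slab -----------------------------------------------------------
    sn = ImageVolume(
        spec.sn_bg_mean + spec.sn_bg_sd * rng.standard_normal(spec.sn_shape), spec.sn_voxel, "sn"
    )
    rois = sn_roi_masks("sn")
    voxel_vol = sn.voxel_volume_mm3
    excess = spec.sn_excess_k * spec.sn_bg_sd if spec.sn_bg_sd > 0 else spec.sn_excess_k
    planted_voxels: dict[str, np.ndarray] = {}
    for region in ("asn_left", "asn_right", "psn_left", "psn_right"):
        target = float(t[f"nm_{region.split('_')[0]}_{region.split('_')[1]}"])
        n_vox = int(round(target / voxel_vol))
        roi = rois[region]
        if n_vox > len(roi):
            raise ValueError(f"planted SN volume {target:.1f} mm^3 exceeds ROI capacity of {region}")
        chosen = roi.voxels[:n_vox]
        sn.data[chosen[:, 0], chosen[:, 1], chosen[:, 2]] += excess
        planted_voxels[region] = chosen
        planted[f"nm_{region}"] = n_vox * voxel_vol
    planted["nm_asn_avg"] = (planted["nm_asn_left"] + planted["nm_asn_right"]) / 2
    planted["nm_psn_avg"] = (planted["nm_psn_left"] + planted["nm_psn_right"]) / 2

    # --- LC slab -----------------------------------------------------------
    lc = ImageVolume(
        spec.lc_bg_mean + spec.lc_bg_sd * rng.standard_normal(spec.lc_shape), spec.lc_voxel, "lc"
    )
    lc_rois = lc_roi_masks("lc")
    # search-ROI tissue is rendered slightly hypointense relative to the pons
    # reference, so the planted cluster is the brightest connected set even
    # when its contrast against the pons is near zero or mildly negative
    for side in ("left", "right"):
        roi = lc_rois[f"lc_{side}"]
        lc.data[roi.index_tuple()] = spec.lc_search_offset * spec.lc_bg_mean + spec.lc_bg_sd * rng.standard_normal(len(roi))
    lc_clusters: dict[tuple, np.ndarray] = {}
    for side in ("left", "right"):
        ci, cj = _LC_CLUSTER_CENTRES[side]
        for sec, slices in _LC_SECTION_SLICES.items():
            contrast = float(t[f"lc_{sec}_{side}"])
            k = slices[1]
            cluster = _plus_cluster(ci, cj, k)
            lc.data[cluster[:, 0], cluster[:, 1], cluster[:, 2]] = (
                spec.lc_bg_mean * (1.0 + contrast)
                + spec.lc_bg_sd * rng.standard_normal(cluster.shape[0])
            )
            lc_clusters[(side, sec)] = cluster
            planted[f"lc_{sec}_{side}"] = contrast
    # per-slice multiplicative gain drift, removed later by the correction step
    if spec.lc_slice_gain_sd > 0:
        gains = 1.0 + spec.lc_slice_gain_sd * rng.standard_normal(spec.lc_shape[2])
        lc.data *= np.clip(gains, 0.5, 1.5)[None, None, :]

    # --- NODDI maps --------------------------------------------------------
    maps = {}
    for metric in ("ndi", "odi", "fwf"):
        data = np.full(spec.noddi_shape, spec.noddi_background) + spec.noddi_noise_sd * rng.standard_normal(
            spec.noddi_shape
        )
        for (region, side), blk in _NODDI_BLOCKS.items():
            true_val = float(t[f"{metric}_{region}_{side}"])
            vox = _block(*blk)
            data[vox[:, 0], vox[:, 1], vox[:, 2]] = true_val + spec.noddi_noise_sd * rng.standard_normal(
                vox.shape[0]
            )
            planted[f"{metric}_{region}_{side}"] = true_val
        maps[metric] = ImageVolume(np.clip(data, 0.0, 1.0), spec.noddi_voxel, "noddi")
    noddi_maps = NoddiMaps(**maps)

    return {
        "sn_image": sn,
        "sn_rois": rois,
        "sn_planted_voxels": planted_voxels,
        "lc_image": lc,
        "lc_rois": lc_rois,
        "lc_clusters": lc_clusters,
        "noddi_maps": noddi_maps,
        "noddi_rois": noddi_roi_masks("noddi"),
        "planted": planted,
    }


SN_LABEL_MAP = {"asn_left": 1, "asn_right": 2, "psn_left": 3, "psn_right": 4, "peduncle": 5}
LC_LABEL_MAP = {"lc_left": 1, "lc_right": 2, "pons": 3}
NODDI_LABEL_MAP = {("asn", "left"): 1, ("asn", "right"): 2, ("psn", "left"): 3, ("psn", "right"): 4}


def _labelmap_volume(shape, voxel, grid_id, rois_with_values) -> ImageVolume:
    data = np.zeros(shape)
    for roi, value in rois_with_values:
        data[roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]] = value
    return ImageVolume(data, voxel, grid_id)


def render_images(truth: pd.DataFrame, spec: ImageSpec, outdir, seed: int = 0) -> dict:
    """Render and write NIfTI volumes + label maps for a whole cohort.

    One directory per subject (sn.nii.gz, lc.nii.gz, ndi/odi/fwf.nii.gz,
    label maps) plus a manifest.json recording the spec, seed and the
    planted truth per subject.  Returns the manifest dict.
    """
    from pathlib import Path

    from .core import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    manifest = {"seed": seed, "image_spec": asdict(spec), "subjects": {}}
    for (_, row), child in zip(truth.iterrows(), ss.spawn(len(truth))):
        rng = np.random.default_rng(child)
        rendered = render_subject_images(row, spec, rng)
        sdir = outdir / str(row["subject_id"])
        sdir.mkdir(exist_ok=True)
        write_volume(rendered["sn_image"], sdir / "sn.nii.gz")
        write_volume(rendered["lc_image"], sdir / "lc.nii.gz")
        for metric in ("ndi", "odi", "fwf"):
            write_volume(rendered["noddi_maps"][metric], sdir / f"{metric}.nii.gz")
        sn_lab = _labelmap_volume(
            spec.sn_shape, spec.sn_voxel, "sn",
            [(rendered["sn_rois"][name], v) for name, v in SN_LABEL_MAP.items()],
        )
        lc_lab = _labelmap_volume(
            spec.lc_shape, spec.lc_voxel, "lc",
            [(rendered["lc_rois"][name], v) for name, v in LC_LABEL_MAP.items()],
        )
        noddi_lab = _labelmap_volume(
            spec.noddi_shape, spec.noddi_voxel, "noddi",
            [
                (roi, NODDI_LABEL_MAP[(roi.label, roi.side)])
                for roi in rendered["noddi_rois"]
            ],
        )
        write_volume(sn_lab, sdir / "sn_labels.nii.gz")
        write_volume(lc_lab, sdir / "lc_labels.nii.gz")
        write_volume(noddi_lab, sdir / "noddi_labels.nii.gz")
        manifest["subjects"][str(row["subject_id"])] = {
            k: float(v) for k, v in rendered["planted"].items()
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# DAT-SPECT table
# ---------------------------------------------------------------------------

def default_normative_model() -> NormativeModel:
    """Declared synthetic normative SBR model (linear in age, by sex)."""
    d = {}
    base = {"striatum": (4.2, 0.30), "putamen": (3.6, 0.30), "caudate": (4.6, 0.35)}
    for roi, (intercept_m, sd) in base.items():
        d[roi] = {
            "M": {"intercept": intercept_m, "age_slope": -0.02, "residual_sd": sd},
            "F": {"intercept": intercept_m + 0.2, "age_slope": -0.02, "residual_sd": sd},
        }
    return NormativeModel.from_dict(d)


def generate_dat(
    cohort: pd.DataFrame,
    model: NormativeModel | None = None,
    n_abnormal_irbd: int = 4,
    n_missing_irbd: int = 1,
    occipital_density: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count-density table for the iRBD subjects, with planted truth.

    ``n_abnormal_irbd`` subjects get a striatal/putaminal normative Z
    planted in (-3.3, -2.1) (flagged abnormal); the rest are drawn clear
    of the -2 boundary.  ``n_missing_irbd`` subjects get no scan.
    Returns ``(counts, dat_truth)``.
    """
    model = model or default_normative_model()
    rng = np.random.default_rng(seed)
    irbd = cohort[cohort["group"] == "iRBD"].reset_index(drop=True)
    n = len(irbd)
    if n_abnormal_irbd + n_missing_irbd > n:
        raise ValueError("more planted abnormal + missing subjects than iRBD subjects")
    order = rng.permutation(n)
    missing_ids = set(irbd.loc[order[:n_missing_irbd], "subject_id"])
    abnormal_ids = set(irbd.loc[order[n_missing_irbd : n_missing_irbd + n_abnormal_irbd], "subject_id"])

    counts_rows, truth_rows = [], []
    for _, r in irbd.iterrows():
        sid = r["subject_id"]
        if sid in missing_ids:
            truth_rows.append({"subject_id": sid, "dat_missing": True, "dat_z_true": np.nan, "dat_abnormal_true": np.nan})
            continue
        if sid in abnormal_ids:
            z = rng.uniform(-3.3, -2.1)
        else:
            z = rng.uniform(-1.7, 1.8)
        row = {"subject_id": sid, "occipital": occipital_density}
        for roi in ("striatum", "putamen", "caudate"):
            z_roi = z * (0.7 if roi == "caudate" else 1.0)
            for side in ("left", "right"):
                zz = z_roi + rng.uniform(-0.1, 0.1)
                e = model.entry(roi, str(r["sex"]))
                sbr_true = e.expected(float(r["age"])) + zz * e.residual_sd
                row[f"{roi}_{side}"] = occipital_density * (1.0 + sbr_true)
        counts_rows.append(row)
        truth_rows.append(
            {"subject_id": sid, "dat_missing": False, "dat_z_true": z, "dat_abnormal_true": sid in abnormal_ids}
        )
    return pd.DataFrame(counts_rows), pd.DataFrame(truth_rows)
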