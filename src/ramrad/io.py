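"""File formats, run configuration and the end-to-end pipeline.

All tabular outputs are UTF-8 TSV/CSV with explicit headers and '.'
decimal separators so runs diff cleanly; volumes are NIfTI-1 with
spacing/origin in the header; transforms are JSON 4x4 row-major
matrices; run configuration is YAML with a versioned schema key and
unknown keys rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import experiments
from .classify_svm import CostMatrix, CvResult
from .feature_selection import FeatureTable
from .mri_radiomics import MODALITIES, CoRegistration, MriVolume, radiomics_vector
from .raman_preprocess import RamanAcquisitionSet, preprocess_site
from .synthetic_cohort import (
    Cohort,
    Histology,
    Site,
    SyntheticConfig,
    generate_cohort,
)

logger = logging.getLogger(__name__)

SITE_COLUMNS = (
    "patient_id",
    "site_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "gs_primary",
    "gs_secondary",
    "isup_gg",
    "hg_percent",
)

CONFIG_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

def write_site_table(sites: list[Site], path: str | Path) -> None:
    rows = []
    for s in sites:
        h = s.histology
        rows.append(
            {
                "patient_id": s.patient_id,
                "site_id": s.site_id,
                "x_mm": s.trus_coords_mm[0],
                "y_mm": s.trus_coords_mm[1],
                "z_mm": s.trus_coords_mm[2],
                "gs_primary": h.gs_primary,
                "gs_secondary": h.gs_secondary,
                "isup_gg": h.isup_gg,
                "hg_percent": "" if h.hg_percent is None else repr(h.hg_percent),
            }
        )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_site_table(path: str | Path) -> list[Site]:
    """Read a site TSV, validating the Gleason/ISUP consistency per row."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "site_id": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing column(s): {sorted(missing)}")
    sites = []
    for k, row in df.iterrows():
        line = k + 2  # header is line 1
        hg = row["hg_percent"]
        hg = None if pd.isna(hg) else float(hg)
        try:
            hist = Histology(
                gs_primary=int(row["gs_primary"]),
                gs_secondary=int(row["gs_secondary"]),
                isup_gg=int(row["isup_gg"]),
                hg_percent=hg,
            )
            site = Site(
                patient_id=row["patient_id"],
                site_id=row["site_id"],
                trus_coords_mm=np.array([row["x_mm"], row["y_mm"], row["z_mm"]]),
                histology=hist,
            )
        except ValueError as err:
            raise ValueError(f"site table line {line} (site {row['site_id']!r}): {err}") from err
        sites.append(site)
    return sites


def sites_to_histology(sites: list[Site]) -> pd.DataFrame:
    rows = {
        s.site_id: {
            "patient_id": s.patient_id,
            "isup_gg": s.histology.isup_gg,
            "hg_percent": np.nan if s.histology.hg_percent is None else s.histology.hg_percent,
        }
        for s in sites
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectra_csv(acq: RamanAcquisitionSet, path: str | Path) -> None:
    """First column the pixel/shift axis, one column per replicate."""
    cols = {"axis": acq.pixel_axis}
    for k in range(acq.n_replicates):
        cols[f"rep{k + 1}"] = acq.replicates[k]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_spectra_csv(path: str | Path, region: str) -> RamanAcquisitionSet:
    df = pd.read_csv(path)
    if df.columns[0] != "axis" or df.shape[1] < 2:
        raise ValueError(f"{path}: expected an 'axis' column plus replicate columns")
    return RamanAcquisitionSet(
        region=region,
        pixel_axis=df["axis"].to_numpy(),
        replicates=df.iloc[:, 1:].to_numpy().T,
    )


def write_processed_csv(shift_axis: np.ndarray, intensity: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"shift_cm-1": shift_axis, "intensity": intensity}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Volumes and transforms
# ---------------------------------------------------------------------------

def write_volume(vol: MriVolume, path: str | Path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing_mm)
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path, modality: str | None = None) -> MriVolume:
    """Read a NIfTI-1 volume; modality from the filename tag unless given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    if modality is None:
        stem = Path(path).name.lower()
        for cand in MODALITIES:
            if cand.lower() in stem:
                modality = cand
                break
        else:
            raise ValueError(f"{path}: cannot infer modality from filename")
    return MriVolume(modality=modality, intensities=data, spacing_mm=spacing, origin_mm=origin)


def write_transform(reg: CoRegistration, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"mri_to_trus": reg.mri_to_trus.tolist()}, indent=1))


def load_transform(path: str | Path) -> CoRegistration:
    data = json.loads(Path(path).read_text())
    return CoRegistration(mri_to_trus=np.array(data["mri_to_trus"], dtype=float))


# ---------------------------------------------------------------------------
# Feature tables and CV results
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Two-row header (feature name, then modality tag); the first two
    columns carry the site and patient identifiers."""
    cols = list(table.values.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_id\tpatient_id\t" + "\t".join(cols) + "\n")
        fh.write("tag\ttag\t" + "\t".join(table.tags[c] for c in cols) + "\n")
        for sid, row in table.values.iterrows():
            fh.write(
                f"{sid}\t{table.patient_ids[sid]}\t"
                + "\t".join(repr(float(v)) for v in row.to_numpy())
                + "\n"
            )


def load_feature_table(path: str | Path) -> FeatureTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[2:]
        tags = fh.readline().rstrip("\n").split("\t")[2:]
        idx, patients, rows = [], [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            idx.append(cells[0])
            patients.append(cells[1])
            rows.append([float(v) for v in cells[2:]])
    values = pd.DataFrame(rows, index=idx, columns=header)
    return FeatureTable(
        values=values,
        tags=pd.Series(tags, index=header),
        patient_ids=pd.Series(patients, index=idx),
    )


def cv_result_to_json(cv: CvResult, path: str | Path) -> None:
    payload = {
        "posteriors": {k: float(v) for k, v in cv.posteriors.items()},
        "labels": {k: int(v) for k, v in cv.labels.items()},
        "mean_n_features": cv.mean_n_features,
        "mean_sv_ratio": cv.mean_sv_ratio,
        "folds": {
            patient: {
                "selected": list(sel.selected),
                "weights": list(sel.weights),
                "fallback_used": sel.fallback_used,
            }
            for patient, sel in cv.fold_selections.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Cohort persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort in the pipeline's on-disk layout."""
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "volumes").mkdir(exist_ok=True)
    (out / "transforms").mkdir(exist_ok=True)
    write_site_table(cohort.sites, out / "sites.tsv")
    for (site_id, region), acq in cohort.acquisitions.items():
        write_spectra_csv(acq, out / "spectra" / f"{site_id}_{region}.csv")
    for patient_id, vols in cohort.volumes.items():
        for modality, vol in vols.items():
            write_volume(vol, out / "volumes" / f"{patient_id}_{modality}.nii")
        write_transform(cohort.registrations[patient_id], out / "transforms" / f"{patient_id}.json")


# ---------------------------------------------------------------------------
# Feature extraction (cohort -> feature table)
# ---------------------------------------------------------------------------

def extract_features(
    cohort: Cohort,
    published_order: bool = False,
    radius_mm: float = 5.0,
    bin_width: float | dict[str, float] = 25.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Preprocess every acquisition and extract radiomics for every site.

    Returns the assembled feature table (FP shifts, HW shifts, r1..r48)
    and the histology table aligned with it.
    """
    fp_axis = cohort.config.region_axis("FP")
    hw_axis = cohort.config.region_axis("HW")
    fp_names = [f"FP_{s:.2f}" for s in fp_axis]
    hw_names = [f"HW_{s:.2f}" for s in hw_axis]
    rad_names = [f"r{i}" for i in range(1, 49)]

    rows = {}
    for site in cohort.sites:
        fp = preprocess_site(cohort.acquisitions[(site.site_id, "FP")], published_order=published_order)
        hw = preprocess_site(cohort.acquisitions[(site.site_id, "HW")], published_order=published_order)
        rad = radiomics_vector(
            site.trus_coords_mm,
            cohort.volumes[site.patient_id],
            cohort.registrations[site.patient_id],
            radius_mm=radius_mm,
            bin_width=bin_width,
        )
        rows[site.site_id] = np.concatenate(
            [fp.intensity, hw.intensity, [rad[n] for n in rad_names]]
        )

    values = pd.DataFrame.from_dict(rows, orient="index", columns=fp_names + hw_names + rad_names)
    tags = pd.Series(
        ["FP"] * len(fp_names) + ["HW"] * len(hw_names) + ["Rad"] * len(rad_names),
        index=fp_names + hw_names + rad_names,
    )
    patient_ids = pd.Series({s.site_id: s.patient_id for s in cohort.sites}).loc[values.index]
    table = FeatureTable(values=values, tags=tags, patient_ids=patient_ids)
    return table, sites_to_histology(cohort.sites)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "schema_version",
    "seed",
    "scheme",
    "combo",
    "max_nf",
    "var_thresh",
    "corr_thresh",
    "cost_matrix",
    "glcm_bin_width",
    "roi_radius_mm",
    "cohort",
}


def load_run_config(path: str | Path) -> dict:
    """YAML run config with a versioned schema; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    version = raw.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "scheme": raw.get("scheme", "gg_gt1"),
        "combo": raw.get("combo", "FP+Rad"),
        "max_nf": int(raw.get("max_nf", 10)),
        "var_thresh": float(raw.get("var_thresh", 0.03)),
        "corr_thresh": float(raw.get("corr_thresh", 0.10)),
        "glcm_bin_width": float(raw.get("glcm_bin_width", 25.0)),
        "roi_radius_mm": float(raw.get("roi_radius_mm", 5.0)),
        "cost_matrix": np.array(raw.get("cost_matrix", [[0, 1], [2, 0]]), dtype=float),
        "cohort": raw.get("cohort", {}),
    }
    if cfg["var_thresh"] <= 0 or cfg["corr_thresh"] <= 0:
        raise ValueError("thresholds must be positive")
    CostMatrix(cfg["cost_matrix"])  # validates
    return cfg


def _digest(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    elif isinstance(obj, np.ndarray):
        payload = obj.tobytes()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Simulate -> preprocess -> radiomics -> experiment drivers.

    Writes the experiment reports, the consensus feature list and a
    structured log of per-stage seeds and output digests under
    ``out_dir``; returns the feature-combination report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, dict] = {}

    cohort_kwargs = dict(config.get("cohort", {}))
    cohort_kwargs["seed"] = config["seed"]
    syn = SyntheticConfig(**cohort_kwargs)
    cohort = generate_cohort(syn)
    log["simulate"] = {"seed": config["seed"], "n_sites": len(cohort.sites)}

    table, histology = extract_features(
        cohort, radius_mm=config["roi_radius_mm"], bin_width=config["glcm_bin_width"]
    )
    log["features"] = {"digest": _digest(table.values), "shape": list(table.values.shape)}

    labels = experiments.assign_labels(histology, config["scheme"])
    keep = labels.index[labels != experiments.EXCLUDED]
    table_used = table.restrict_sites(keep)
    y = labels.loc[keep]
    log["labels"] = {
        "scheme": config["scheme"],
        "n_sites": int(len(keep)),
        "n_positive": int((y == 1).sum()),
    }

    cost = CostMatrix(config["cost_matrix"])
    combo_report, combo_cvs = experiments.feature_combination_experiment(
        table_used, y, max_nf=config["max_nf"], cost=cost
    )
    combo_report.to_csv(out / "combinations.tsv", sep="\t")
    cv_result_to_json(combo_cvs[config["combo"]], out / "cv_result.json")

    n_folds = combo_cvs[config["combo"]].n_folds
    consensus = experiments.consensus_features(
        combo_cvs[config["combo"]], min_count=max(n_folds // 2 + 1, 1)
    )
    consensus.to_csv(out / "consensus.tsv", sep="\t", header=["n_folds"])
    log["experiment"] = {"digest": _digest(combo_report), "combo": config["combo"]}

    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    logger.info("pipeline complete: %s", out)
    return combo_report
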