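"""Readers and writers for the cohort table, NIfTI volumes and result files."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .voxels import ClusterRecord, VolumeImage

COHORT_ID_COLUMNS = ["subject_id", "family_id", "zygosity", "sex"]


def write_cohort_csv(cohort: pd.DataFrame, path) -> Path:
    """Write the cohort table, dropping generator-internal columns
    (those prefixed with an underscore)."""
    path = Path(path)
    public = [c for c in cohort.columns if not c.startswith("_")]
    cohort[public].to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    return df


def write_volumes(volumes: list[VolumeImage], out_dir,
                  manifest_name: str = "manifest.json") -> Path:
    """Write one NIfTI-1 file per subject plus a JSON manifest
    subject_id -> relative path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for vol in volumes:
        fname = f"{vol.subject_id}.nii"
        img = nib.Nifti1Image(vol.grid.astype(np.float32), vol.affine)
        nib.save(img, out_dir / fname)
        manifest[vol.subject_id] = fname
    mpath = out_dir / manifest_name
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_volumes(manifest_path) -> list[VolumeImage]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    vols = []
    for sid, rel in manifest.items():
        img = nib.load(base / rel)
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        vols.append(VolumeImage(np.asanyarray(img.dataobj, dtype=np.float64),
                                voxel_size=vs, subject_id=sid,
                                affine=np.asarray(img.affine)))
    return vols


def write_nifti(grid: np.ndarray, path, voxel_size=(2.0, 2.0, 2.0),
                affine=None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), path)
    return path


def write_cluster_table(clusters: list[ClusterRecord], path,
                        voxel_size=(2.0, 2.0, 2.0)) -> Path:
    path = Path(path)
    rows = []
    for cl in clusters:
        d = cl.to_dict()
        d["peak_mm_x"] = cl.peak_ijk[0] * voxel_size[0]
        d["peak_mm_y"] = cl.peak_ijk[1] * voxel_size[1]
        d["peak_mm_z"] = cl.peak_ijk[2] * voxel_size[2]
        rows.append(d)
    cols = ["peak_i", "peak_j", "peak_k", "peak_mm_x", "peak_mm_y",
            "peak_mm_z", "peak_t", "size", "sign"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(data, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, indent=1, sort_keys=True,
                               cls=_NumpyEncoder))
    return path
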