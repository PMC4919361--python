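"""NIfTI and tabular input/output for cohorts, masks and maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import SubjectScan
from .features import BrainMask


def write_nifti(volume, voxel_size, path) -> None:
    """Write a 3-D or 4-D float volume with a diagonal affine from voxel size."""
    volume = np.asarray(volume, dtype=np.float64)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms((*voxel_size, *([1.0] if volume.ndim == 4 else [])))
    nib.save(img, str(path))


def read_nifti(path):
    """Read a NIfTI file; returns ``(data, voxel_size)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # malformed header / payload
        raise ValueError(f"cannot read NIfTI {path}: {exc}") from exc
    return data, voxel_size


def save_cohort(scans, out_dir, mask: BrainMask | None = None) -> Path:
    """Write per-subject NIfTIs, a participants table, and optionally a mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        write_nifti(scan.structural, scan.voxel_size,
                    out_dir / f"{scan.subject_id}_structural.nii")
        write_nifti(scan.functional, scan.voxel_size,
                    out_dir / f"{scan.subject_id}_functional.nii")
        rows.append({"subject_id": scan.subject_id, "label": scan.label,
                     "tr": scan.tr})
    pd.DataFrame(rows).to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    if mask is not None:
        write_nifti(mask.grid.astype(np.float64), scans[0].voxel_size,
                    out_dir / "mask.nii")
    return out_dir


def load_cohort(cohort_dir) -> list[SubjectScan]:
    """Read a cohort written by :func:`save_cohort`."""
    cohort_dir = Path(cohort_dir)
    table = cohort_dir / "participants.tsv"
    if not table.exists():
        raise FileNotFoundError(f"no participants table at {table}")
    df = pd.read_csv(table, sep="\t")
    scans = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        structural, voxel_size = read_nifti(cohort_dir / f"{sid}_structural.nii")
        functional, _ = read_nifti(cohort_dir / f"{sid}_functional.nii")
        scans.append(SubjectScan(subject_id=sid, label=int(row["label"]),
                                 structural=structural, functional=functional,
                                 tr=float(row.get("tr", 2.0)),
                                 voxel_size=voxel_size))
    return scans


def load_mask(path) -> BrainMask:
    data, _ = read_nifti(path)
    return BrainMask(data > 0.5)
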