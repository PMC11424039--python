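"""Readers and writers for the standard neuroimaging and tabular formats.

Streamlines travel as TCK (via nibabel), signals and label volumes as
NIfTI, gradient tables as FSL-style bvals/bvecs text files, connectomes
as CSV matrices with a TSV node-metadata sidecar, and cohorts as a
directory of connectome CSVs plus a subjects TSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.tck import TckFile

from .cohort import SubjectRecord
from .connectome import Connectome
from .parcellation import NetworkAssignment, Parcellation
from .phantom import Streamline, Tractogram, VoxelGrid
from .scheme import AcquisitionScheme

__all__ = [
    "save_tck",
    "load_tck",
    "save_nifti",
    "load_nifti",
    "save_gradient_table",
    "load_gradient_table",
    "save_connectome",
    "load_connectome",
    "save_assignment",
    "load_assignment",
    "save_cohort",
    "load_cohort",
]


def save_tck(tractogram: Tractogram, path: str | Path) -> None:
    nt = NibTractogram([s.points for s in tractogram.streamlines],
                       affine_to_rasmm=np.eye(4))
    TckFile(nt).save(str(path))


def load_tck(path: str | Path) -> Tractogram:
    tck = nib.streamlines.load(str(path))
    return Tractogram([Streamline(np.asarray(s)) for s in tck.streamlines])


def save_nifti(volume: np.ndarray, path: str | Path, voxel_size: float = 2.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), voxel_size


def save_gradient_table(scheme: AcquisitionScheme, bvals_path, bvecs_path) -> None:
    """FSL convention: bvals one row; bvecs three rows (x, y, z)."""
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.8f")


def load_gradient_table(bvals_path, bvecs_path=None) -> AcquisitionScheme:
    """Read bvals/bvecs files, or a single 4-column (bval, gx, gy, gz) table."""
    if bvecs_path is None:
        table = np.loadtxt(bvals_path)
        if table.ndim != 2 or table.shape[1] != 4:
            raise ValueError("single-file gradient table must have 4 columns")
        return AcquisitionScheme(table[:, 0], table[:, 1:])
    bvals = np.atleast_1d(np.loadtxt(bvals_path)).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return AcquisitionScheme(bvals, bvecs)


def save_connectome(conn: Connectome, csv_path: str | Path,
                    sidecar_path: str | Path | None = None) -> None:
    labels = [int(x) for x in conn.labels]
    pd.DataFrame(conn.matrix, index=labels, columns=labels).to_csv(csv_path)
    if sidecar_path is not None:
        meta = pd.DataFrame(
            {
                "roi": labels,
                "name": [conn.roi_names.get(r, "") for r in labels],
                "group": [conn.groups.get(r, "") for r in labels],
            }
        )
        meta.to_csv(sidecar_path, sep="\t", index=False)


def load_connectome(csv_path: str | Path,
                    sidecar_path: str | Path | None = None,
                    weighting: str = "IASF") -> Connectome:
    df = pd.read_csv(csv_path, index_col=0)
    labels = np.array([int(c) for c in df.columns])
    roi_names: dict[int, str] = {}
    groups: dict[int, str] = {}
    if sidecar_path is not None:
        meta = pd.read_csv(sidecar_path, sep="\t").fillna("")
        for _, row in meta.iterrows():
            if row["name"]:
                roi_names[int(row["roi"])] = str(row["name"])
            if row["group"]:
                groups[int(row["roi"])] = str(row["group"])
    return Connectome(df.values, labels, weighting=weighting,
                      roi_names=roi_names, groups=groups)


def save_assignment(assignment: NetworkAssignment, path: str | Path) -> None:
    rows = [
        {"roi": r, "group": g, "agreement": assignment.agreement.get(r, np.nan),
         "discarded": False}
        for r, g in sorted(assignment.mapping.items())
    ]
    rows += [
        {"roi": r, "group": "", "agreement": assignment.agreement.get(r, np.nan),
         "discarded": True}
        for r in assignment.discarded
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_assignment(path: str | Path) -> NetworkAssignment:
    df = pd.read_csv(path, sep="\t").fillna({"group": ""})
    mapping = {
        int(r.roi): str(r.group)
        for r in df.itertuples()
        if not r.discarded and r.group
    }
    discarded = [int(r.roi) for r in df.itertuples() if r.discarded]
    agreement = {
        int(r.roi): float(r.agreement)
        for r in df.itertuples()
        if np.isfinite(r.agreement)
    }
    return NetworkAssignment(mapping, discarded, agreement)


def save_cohort(cohort: list[SubjectRecord], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        save_connectome(rec.connectome, out / f"{rec.id}_connectome.csv")
        rows.append({"id": rec.id, "age": rec.age, "sex": rec.sex, "icv": rec.icv})
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)


def load_cohort(in_dir: str | Path,
                assignment: NetworkAssignment | None = None) -> list[SubjectRecord]:
    indir = Path(in_dir)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t")
    groups = dict(assignment.mapping) if assignment is not None else {}
    cohort = []
    for row in subjects.itertuples():
        conn = load_connectome(indir / f"{row.id}_connectome.csv")
        if groups:
            conn.groups = groups
        cohort.append(
            SubjectRecord(id=str(row.id), age=float(row.age), sex=str(row.sex),
                          icv=float(row.icv), connectome=conn)
        )
    return cohort
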