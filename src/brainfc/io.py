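"""File formats: ROI time-series TSV, subject manifest, FC TSV, NIfTI maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from brainfc.connectivity import FCMatrix, RoiTimeSeries


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.roi_labels).to_csv(path, sep="\t", index=False)


def read_roi_timeseries(path: str | Path, tr_seconds: float = 0.8,
                        subject_id: str = "") -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(df.to_numpy(dtype=float), list(df.columns),
                         tr_seconds, subject_id or Path(path).stem)


def write_manifest(path: str | Path, rows: pd.DataFrame) -> None:
    """Manifest TSV: subject_id, file, label, plus covariate columns."""
    required = {"subject_id", "file", "label"}
    if not required <= set(rows.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    rows.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "file", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    return df


def load_cohort_from_manifest(manifest_path: str | Path, tr_seconds: float = 0.8):
    from brainfc.synthetic import Cohort

    mf = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    subjects = []
    for _, row in mf.iterrows():
        p = Path(row["file"])
        if not p.is_absolute():
            p = root / p
        subjects.append(read_roi_timeseries(p, tr_seconds, str(row["subject_id"])))
    covariates = mf.drop(columns=["subject_id", "file", "label"]).reset_index(drop=True)
    if covariates.shape[1] == 0:
        covariates = pd.DataFrame(index=range(len(mf)))
    labels = mf["label"].to_numpy(dtype=int)
    return Cohort(subjects, labels, covariates)


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    pd.DataFrame(fc.values, index=fc.roi_labels, columns=fc.roi_labels).to_csv(
        path, sep="\t")


def read_fc_matrix(path: str | Path, method_tag: str = "PC") -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(df.to_numpy(dtype=float), method_tag, list(df.columns))


def write_voxel_map(vmap, path: str | Path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vmap.values.astype(np.float32), affine), str(path))


def read_voxel_series(path: str | Path, mask_path: str | Path,
                      tr_seconds: float | None = None):
    import nibabel as nib

    from brainfc.voxel import VoxelSeries

    img = nib.load(str(path))
    mask = nib.load(str(mask_path)).get_fdata() > 0
    tr = tr_seconds
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.8
    voxdim = tuple(float(v) for v in img.header.get_zooms()[:3])
    return VoxelSeries(img.get_fdata(), tr, mask, voxdim)
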