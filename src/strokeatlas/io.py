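"""Readers and writers: clinical CSV, NIfTI masks and maps, landmarks.

Masks are stored as unsigned 8-bit NIfTI-1, counts as 32-bit int, map
accumulators as 64-bit float (so merged bundles round-trip exactly).
The clinical table is a CSV with one row per case; empty cells are
missing values.  A stroke map persists as a directory of three NIfTI
volumes (sum, weight, count) plus a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    AtlasSpace,
    CaseRecord,
    ContourFile,
    GridMismatchError,
    SelectionSpec,
    StrokeMap,
    MRS_DAYS,
    BI_DAYS,
)
from .normalization import LandmarkSet

__all__ = [
    "CLINICAL_COLUMNS",
    "ClinicalTableError",
    "read_clinical_table",
    "write_clinical_table",
    "read_mask",
    "write_mask",
    "read_map",
    "write_map",
    "read_landmarks",
    "write_landmarks",
    "write_cohort",
    "read_cohort_dir",
]

CLINICAL_COLUMNS = (
    ["case_id", "infarct_volume_cm3", "nihss_admission", "nihss_day7"]
    + [f"mrs{d}" for d in MRS_DAYS]
    + [f"bi{d}" for d in BI_DAYS]
)


class ClinicalTableError(ValueError):
    pass


def _cell(row, col, rownum):
    v = row[col]
    if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
        return None
    return v


def read_clinical_table(path) -> list[CaseRecord]:
    """Parse and validate the clinical CSV.

    Raises ClinicalTableError with a row- and column-addressed message
    for missing columns, duplicate ids and out-of-range values.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ClinicalTableError(f"missing required columns: {missing_cols}")
    if df["case_id"].duplicated().any():
        dups = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ClinicalTableError(f"duplicate case ids: {dups}")
    records = []
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        try:
            records.append(
                CaseRecord(
                    case_id=str(row["case_id"]),
                    infarct_volume_cm3=float(row["infarct_volume_cm3"]),
                    nihss_admission=_cell(row, "nihss_admission", rownum),
                    nihss_day7=_cell(row, "nihss_day7", rownum),
                    mrs={d: _cell(row, f"mrs{d}", rownum) for d in MRS_DAYS},
                    bi={d: _cell(row, f"bi{d}", rownum) for d in BI_DAYS},
                )
            )
        except (ValueError, TypeError) as exc:
            raise ClinicalTableError(f"row {rownum}: {exc}") from exc
    return records


def write_clinical_table(records: Sequence[CaseRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "infarct_volume_cm3": r.infarct_volume_cm3,
            "nihss_admission": r.nihss_admission,
            "nihss_day7": r.nihss_day7,
        }
        for d in MRS_DAYS:
            row[f"mrs{d}"] = r.mrs[d]
        for d in BI_DAYS:
            row[f"bi{d}"] = r.bi[d]
        rows.append(row)
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def _space_of_image(img) -> AtlasSpace:
    zooms = img.header.get_zooms()[:3]
    return AtlasSpace(dims=tuple(img.shape[:3]), voxel_size=tuple(float(z) for z in zooms))


def read_mask(
    path, case_id: Optional[str] = None, frame: str = "atlas",
    space: Optional[AtlasSpace] = None,
) -> ContourFile:
    """Load a binary mask; the NIfTI affine carries the frame pose."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    file_space = _space_of_image(img)
    if space is not None and tuple(space.dims) != tuple(file_space.dims):
        raise GridMismatchError(
            f"{path}: dims {file_space.dims} do not match declared {space.dims}"
        )
    return ContourFile(
        case_id=case_id or Path(path).stem.replace(".nii", ""),
        mask=data,
        space=space or file_space,
        frame=frame,
        affine=np.asarray(img.affine),
    )


def write_mask(contour: ContourFile, path) -> None:
    img = nib.Nifti1Image(
        contour.mask.astype(np.uint8), affine=contour.affine
    )
    nib.save(img, str(path))


def write_map(psm: StrokeMap, out_dir) -> None:
    """Persist a stroke map as sum/weight/count volumes + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = psm.space.affine()
    nib.save(nib.Nifti1Image(psm.sum_map.astype(np.float64), aff), str(out / "sum.nii"))
    nib.save(
        nib.Nifti1Image(psm.weight_map.astype(np.float64), aff), str(out / "weight.nii")
    )
    nib.save(
        nib.Nifti1Image(psm.count_map.astype(np.int32), aff), str(out / "count.nii")
    )
    vol_hi = psm.selection.volume_range[1]
    sidecar = {
        "parameter": psm.parameter,
        "weight_id": psm.weight_id,
        "n_cases": psm.n_cases,
        "case_ids": list(psm.case_ids),
        "dims": list(psm.space.dims),
        "voxel_size": list(psm.space.voxel_size),
        "selection": {
            "volume_range": [
                psm.selection.volume_range[0],
                None if math.isinf(vol_hi) else vol_hi,
            ],
            "nihssa_range": list(psm.selection.nihssa_range),
            "nihss7_range": list(psm.selection.nihss7_range),
        },
    }
    (out / "map.json").write_text(json.dumps(sidecar, indent=1))


def read_map(map_dir) -> StrokeMap:
    d = Path(map_dir)
    sidecar = json.loads((d / "map.json").read_text())
    space = AtlasSpace(
        dims=tuple(sidecar["dims"]), voxel_size=tuple(sidecar["voxel_size"])
    )
    arrays = {}
    for name in ("sum", "weight", "count"):
        img = nib.load(str(d / f"{name}.nii"))
        if tuple(img.shape[:3]) != tuple(space.dims):
            raise GridMismatchError(
                f"{name}.nii dims {img.shape[:3]} do not match sidecar {space.dims}"
            )
        arrays[name] = np.asarray(img.dataobj)
    sel = sidecar["selection"]
    vol_lo, vol_hi = sel["volume_range"]
    selection = SelectionSpec(
        volume_range=(vol_lo, math.inf if vol_hi is None else vol_hi),
        nihssa_range=tuple(sel["nihssa_range"]),
        nihss7_range=tuple(sel["nihss7_range"]),
    )
    return StrokeMap(
        parameter=sidecar["parameter"],
        weight_id=sidecar["weight_id"],
        sum_map=arrays["sum"],
        weight_map=arrays["weight"],
        count_map=arrays["count"],
        n_cases=sidecar["n_cases"],
        selection=selection,
        space=space,
        case_ids=tuple(sidecar["case_ids"]),
    )


def read_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(json.loads(Path(path).read_text()))


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.as_dict(), indent=1))


def write_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort in the on-disk layout the CLI consumes:
    masks/<id>.nii (native frame), landmarks/<id>.json, clinical.csv,
    and ground_truth/<param>.nii."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    write_clinical_table(cohort.records, out / "clinical.csv")
    for case in cohort.cases:
        cid = case.record.case_id
        write_mask(case.native_contour, out / "masks" / f"{cid}.nii")
        write_landmarks(case.landmarks, out / "landmarks" / f"{cid}.json")
    aff = cohort.space.affine()
    for parameter, fld in cohort.fields.items():
        nib.save(
            nib.Nifti1Image(fld.values.astype(np.float64), aff),
            str(out / "ground_truth" / f"{parameter}.nii"),
        )
    meta = {
        "seed": cohort.seed,
        "sigma": cohort.sigma,
        "n": len(cohort.cases),
        "dims": list(cohort.space.dims),
        "voxel_size": list(cohort.space.voxel_size),
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=1))


def read_cohort_dir(cohort_dir):
    """Load (records, native contours, landmark sets, space) from disk."""
    d = Path(cohort_dir)
    records = read_clinical_table(d / "clinical.csv")
    meta = json.loads((d / "cohort.json").read_text())
    space = AtlasSpace(dims=tuple(meta["dims"]), voxel_size=tuple(meta["voxel_size"]))
    contours = {}
    landmarks = {}
    for r in records:
        contours[r.case_id] = read_mask(
            d / "masks" / f"{r.case_id}.nii", case_id=r.case_id, frame="native"
        )
        landmarks[r.case_id] = read_landmarks(d / "landmarks" / f"{r.case_id}.json")
    return records, contours, landmarks, space
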