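"""File input/output: NIfTI and DICOM volumes, ROI specs, biomarker tables.

Conventions pinned here so seeds and ROI indices are portable:

* in-memory grids are indexed ``(z, y, x)`` with spacing in mm;
* NIfTI stores ``(x, y, z)``, so arrays are transposed on read/write and
  the affine is diagonal in the voxel spacing;
* DICOM series are sorted by slice position along the normal and the
  rescale slope/intercept is applied to yield HU;
* biomarker tables are CSV with the fixed column order
  ``subject_id, group, bin_1.25 .. bin_98.75, mean_avtv, pe_910, pe_950,
  rv_nl, rv_dl, r_dl_nl``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FractionMap, HUVolume, RoiSpec
from .ravh import BIN_CENTERS, RAVH, BiomarkerSet
from .segment import BinaryMask

__all__ = [
    "read_nifti_volume",
    "write_nifti",
    "read_dicom_series",
    "read_roi_specs",
    "write_roi_specs",
    "biomarker_frame",
    "write_biomarker_csv",
    "read_biomarker_csv",
]

BIOMARKER_COLUMNS = (
    ["subject_id", "group"]
    + [f"bin_{c:.2f}" for c in BIN_CENTERS]
    + ["mean_avtv", "pe_910", "pe_950", "rv_nl", "rv_dl", "r_dl_nl"]
)


def _nifti_affine(spacing_zyx) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    return np.diag([sx, sy, sz, 1.0])


def read_nifti_volume(path: str | Path, provenance: str = "") -> HUVolume:
    """Read a NIfTI volume as HU, reordering axes to (z, y, x)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return HUVolume(np.ascontiguousarray(data.T), (float(zooms[2]), float(zooms[1]), float(zooms[0])),
                    provenance=provenance or str(path))


def write_nifti(obj: HUVolume | FractionMap | BinaryMask, path: str | Path) -> None:
    """Write a grid as NIfTI: float32 for HU/fractions, uint8 for masks."""
    import nibabel as nib

    if isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8)
    else:
        data = obj.values.astype(np.float32)
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), _nifti_affine(obj.spacing))
    zooms = (obj.spacing[2], obj.spacing[1], obj.spacing[0])
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_dicom_series(directory: str | Path) -> HUVolume:
    """Read a directory of single-frame DICOM slices as one HU volume.

    Slices are sorted by position along the slice normal; the rescale
    slope and intercept of each slice map stored values to HU.
    """
    import pydicom

    paths = sorted(p for p in Path(directory).iterdir() if p.is_file())
    slices = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    arrays = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    volume = np.stack(arrays, axis=0)

    ds0 = slices[0]
    row_sp, col_sp = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    if len(slices) > 1 and hasattr(ds0, "ImagePositionPatient"):
        dz = abs(z_of(slices[1]) - z_of(slices[0]))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    return HUVolume(volume, (dz or 1.0, row_sp, col_sp), provenance=str(directory))


def read_roi_specs(path: str | Path) -> list[RoiSpec]:
    """Read a JSON list of ROI specifications."""
    with open(path) as fh:
        entries = json.load(fh)
    return [
        RoiSpec(
            shape=e["shape"],
            center=tuple(float(c) for c in e["center"]),
            extent=tuple(float(x) for x in e["extent"]),
            label=e.get("label", ""),
        )
        for e in entries
    ]


def write_roi_specs(rois: list[RoiSpec], path: str | Path) -> None:
    entries = [
        {"shape": r.shape, "center": list(r.center), "extent": list(r.extent), "label": r.label}
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)


def biomarker_frame(rows: list[tuple[str, str, RAVH, BiomarkerSet]]) -> pd.DataFrame:
    """Assemble (subject_id, group, RAVH, biomarkers) rows into the
    fixed-column biomarker table."""
    records = []
    for subject_id, group, ravh, markers in rows:
        rec: dict[str, object] = {"subject_id": subject_id, "group": group}
        for c, rv in zip(BIN_CENTERS, ravh.relative_volumes):
            rec[f"bin_{c:.2f}"] = rv
        rec.update(markers.as_dict())
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=BIOMARKER_COLUMNS)


def write_biomarker_csv(rows, path: str | Path) -> None:
    biomarker_frame(rows).to_csv(path, index=False)


def read_biomarker_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"biomarker table {path} lacks columns {missing}")
    return df
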