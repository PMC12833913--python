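"""Reading and writing quantitative maps and cohort manifests.

Maps travel in two dialects:

* NIfTI (physical units, float) via nibabel, with the pixel spacing in
  the affine — the analysis-friendly form.
* A DICOM dialect via pydicom that stores unsigned 16-bit integers with
  ``RescaleSlope`` 0.1 (stored value = physical x 10), matching the
  scanner export convention for these maps.

The cohort manifest is a CSV with one row per subject
(subject_id, split, seed, n_lesions, lesion_classes).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import CohortMember, QuantMap, RESCALE_SLOPE

__all__ = [
    "write_nifti", "read_nifti", "write_dicom", "read_dicom",
    "write_manifest", "read_manifest", "load_lesion_roi_table",
]

_PARAM_TAG = "qmapsr_parameter"


def write_nifti(qmap: QuantMap, path) -> None:
    import nibabel as nib
    affine = np.diag([qmap.pixel_spacing, qmap.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(qmap.values.astype(np.float32), affine)
    img.header["descrip"] = f"{_PARAM_TAG}={qmap.parameter}".encode()
    nib.save(img, str(path))


def read_nifti(path, parameter: str | None = None) -> QuantMap:
    import nibabel as nib
    img = nib.load(str(path))
    if parameter is None:
        desc = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
        parameter = desc.split("=", 1)[1].split("\x00")[0] if "=" in desc else "T1"
    spacing = float(img.header.get_zooms()[0])
    return QuantMap(np.asarray(img.dataobj, dtype=float), parameter, spacing)


def write_dicom(qmap: QuantMap, path) -> None:
    """Secondary-capture DICOM with integer pixels and RescaleSlope 0.1."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.SeriesDescription = f"{qmap.parameter} map"
    ds.Rows, ds.Columns = qmap.grid
    ds.PixelSpacing = [f"{qmap.pixel_spacing:.6f}"] * 2
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned
    ds.RescaleSlope = str(qmap.rescale_slope)
    ds.RescaleIntercept = "0"
    stored = np.clip(np.round(qmap.values / qmap.rescale_slope), 0, 65535)
    ds.PixelData = stored.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom(path, parameter: str | None = None) -> QuantMap:
    import pydicom
    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", RESCALE_SLOPE))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = ds.pixel_array.astype(float) * slope + intercept
    if parameter is None:
        desc = str(getattr(ds, "SeriesDescription", "T1 map"))
        parameter = desc.split()[0]
    spacing = float(ds.PixelSpacing[0])
    return QuantMap(values, parameter, spacing, rescale_slope=slope)


def write_manifest(members: list[CohortMember], path) -> None:
    pd.DataFrame([{
        "subject_id": m.subject_id, "split": m.split, "seed": m.seed,
        "n_lesions": m.n_lesions,
        "lesion_classes": "|".join(m.lesion_classes),
    } for m in members]).to_csv(path, index=False)


def read_manifest(path) -> list[CohortMember]:
    df = pd.read_csv(path, keep_default_na=False)
    return [CohortMember(
        subject_id=str(r.subject_id), seed=int(r.seed), split=str(r.split),
        n_lesions=int(r.n_lesions),
        lesion_classes=tuple(c for c in str(r.lesion_classes).split("|") if c),
    ) for r in df.itertuples()]


def load_lesion_roi_table(path=None) -> pd.DataFrame:
    """The packaged 12-ROI lesion comparison table (or a user CSV with the
    same columns: roi_id, description, t1_dl, t1_routine, ...)."""
    if path is None:
        path = Path(__file__).parent / "data" / "lesion_rois.csv"
    return pd.read_csv(path)
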