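"""Volume and mask I/O.

NIfTI (compressed) is the canonical interchange format; DICOM CT/MR series
and RTSTRUCT body contours are ingest-only.  Internally every volume is held
as ``(slice, row, col)`` with rows running anterior -> posterior; NIfTI data
is reoriented to/from the closest RAS+ canonical form on the way through, so
write-then-read round trips are bit-identical and externally oriented files
land in the internal convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import Volume3D
from .phantom import PhantomPatient


class IngestionError(ValueError):
    """A series or mask cannot be read consistently."""


def _to_xyz(data: np.ndarray) -> np.ndarray:
    # internal (slice, row, col) -> RAS-ish (x=col, y=flipped row, z=slice)
    return np.ascontiguousarray(data.transpose(2, 1, 0)[:, ::-1, :])


def _from_xyz(data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(data[:, ::-1, :].transpose(2, 1, 0))


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as compressed NIfTI with an RAS+ affine."""
    sz, sr, sc = volume.spacing
    affine = np.diag([sc, sr, sz, 1.0])
    img = nib.Nifti1Image(_to_xyz(volume.data), affine)
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    """Read a NIfTI file or a DICOM series directory into a Volume3D.

    NIfTI input is reoriented to canonical RAS+ before conversion to the
    internal axis order.  DICOM series are sorted by slice position and the
    HU rescale slope/intercept is applied (missing rescale tags produce a
    warning and raw stored values).
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    zooms = img.header.get_zooms()[:3]
    data = _from_xyz(np.asarray(img.dataobj, dtype=np.float64))
    return Volume3D(data, spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])))


def _read_dicom_series(directory: Path) -> Volume3D:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    datasets = [pydicom.dcmread(str(p)) for p in files if p.is_file()]
    datasets = [d for d in datasets if hasattr(d, "pixel_array")]
    if not datasets:
        raise IngestionError(f"no DICOM images found in {directory}")
    orientations = {tuple(np.round(d.ImageOrientationPatient, 4)) for d in datasets
                    if hasattr(d, "ImageOrientationPatient")}
    if len(orientations) > 1:
        raise IngestionError("mixed-orientation DICOM series")

    def z_of(d):
        if hasattr(d, "ImagePositionPatient"):
            return float(d.ImagePositionPatient[2])
        return float(getattr(d, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    planes = []
    for d in datasets:
        arr = d.pixel_array.astype(np.float64)
        slope = getattr(d, "RescaleSlope", None)
        intercept = getattr(d, "RescaleIntercept", None)
        if slope is None or intercept is None:
            warnings.warn("missing rescale tags; returning raw stored values", stacklevel=2)
        else:
            arr = arr * float(slope) + float(intercept)
        planes.append(arr)
    first = datasets[0]
    row_sp, col_sp = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(datasets) > 1:
        slice_sp = abs(z_of(datasets[1]) - z_of(datasets[0])) or 1.0
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    return Volume3D(np.stack(planes), spacing=(slice_sp, row_sp, col_sp))


def write_mask(mask: np.ndarray, path, spacing=(3.0, 1.5, 1.5)) -> None:
    write_volume(Volume3D(mask.astype(np.uint8), spacing), path)


def read_body_mask(path, reference: Volume3D | None = None, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Read a body mask from a NIfTI label volume or a DICOM RTSTRUCT.

    RTSTRUCT contours (patient-coordinate polygons) require ``reference``
    for the voxel grid; polygons are rasterized slice-by-slice.  An all-ones
    mask is accepted but flagged as suspicious (no background voxel).
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        if reference is None:
            raise IngestionError("RTSTRUCT ingestion needs a reference volume")
        mask = _rasterize_rtstruct(path, reference, origin)
    else:
        mask = read_volume(path).data > 0.5
    if not mask.any():
        raise IngestionError("body mask is empty")
    if mask.all():
        warnings.warn("body mask covers every voxel (no background)", stacklevel=2)
    return mask


def _rasterize_rtstruct(path: Path, reference: Volume3D, origin) -> np.ndarray:
    import pydicom
    from skimage.draw import polygon

    ds = pydicom.dcmread(str(path))
    mask = np.zeros(reference.shape, dtype=bool)
    sz, sr, sc = reference.spacing
    oz, orow, ocol = origin
    for roi in ds.ROIContourSequence:
        for contour in roi.ContourSequence:
            pts = np.asarray(contour.ContourData, dtype=np.float64).reshape(-1, 3)
            z = int(round((pts[0, 2] - oz) / sz))
            if not 0 <= z < reference.shape[0]:
                continue
            rows = (pts[:, 1] - orow) / sr
            cols = (pts[:, 0] - ocol) / sc
            rr, cc = polygon(rows, cols, shape=reference.shape[1:])
            mask[z, rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# phantom patient directories
# ---------------------------------------------------------------------------

_PATIENT_FILES = ("mri.nii.gz", "ct.nii.gz", "body.nii.gz", "labels.nii.gz")


def save_patient(patient: PhantomPatient, directory) -> None:
    """One NIfTI file per volume inside a per-patient directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spacing = patient.mri.spacing
    write_volume(patient.mri, directory / "mri.nii.gz")
    write_volume(patient.ct, directory / "ct.nii.gz")
    write_mask(patient.body, directory / "body.nii.gz", spacing)
    write_volume(Volume3D(patient.labels.astype(np.int16), spacing), directory / "labels.nii.gz")


def load_patient(directory, patient_id: int | None = None) -> PhantomPatient:
    directory = Path(directory)
    for name in _PATIENT_FILES:
        if not (directory / name).exists():
            raise IngestionError(f"missing {name} in {directory}")
    if patient_id is None:
        try:
            patient_id = int(str(directory.name).split("_")[-1])
        except ValueError:
            patient_id = 0
    return PhantomPatient(
        mri=read_volume(directory / "mri.nii.gz"),
        ct=read_volume(directory / "ct.nii.gz"),
        body=read_volume(directory / "body.nii.gz").data > 0.5,
        labels=read_volume(directory / "labels.nii.gz").data.astype(np.int8),
        patient_id=patient_id,
    )


def save_cohort(cohort: list[PhantomPatient], directory) -> None:
    directory = Path(directory)
    for patient in cohort:
        save_patient(patient, directory / f"patient_{patient.patient_id:03d}")


def load_cohort(directory) -> list[PhantomPatient]:
    directory = Path(directory)
    dirs = sorted(p for p in directory.iterdir() if p.is_dir() and p.name.startswith("patient_"))
    if not dirs:
        raise IngestionError(f"no patient_* directories in {directory}")
    return [load_patient(p) for p in dirs]
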