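"""Radiotherapy DICOM I/O: CT series, RTSTRUCT contour sets, RTDOSE grids.

Readers accept clinical-style axial, axis-aligned files; writers emit minimal
but standard-conformant datasets (single frame of reference, identity
orientation, no couch rotation) so synthetic fixtures can be opened in
third-party viewers.  A single-file compressed bundle (NumPy ``.npz`` with a
JSON header) stores a whole :class:`PatientCase` for fast round-tripping;
DICOM remains the interchange format.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids_structures import ScalarVolume, Structure, StructureSet, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "PatientCase",
    "read_ct_series",
    "write_ct_series",
    "read_rtstruct",
    "write_rtstruct",
    "read_rtdose",
    "write_rtdose",
    "read_calibration_table",
    "save_case",
    "load_case",
]

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"


@dataclass
class PatientCase:
    """One patient's inputs: CT, contours, named dose volumes, prescription.

    All dose volumes must share one grid; the prescription dose is in Gy.
    """

    ct: ScalarVolume
    structures: StructureSet
    doses: dict[str, ScalarVolume] = field(default_factory=dict)
    prescription_dose: float = 0.0

    def __post_init__(self) -> None:
        if self.ct.unit != "HU":
            raise ValueError("PatientCase.ct must be an HU volume")
        grids = {id(d.grid): d.grid for d in self.doses.values()}
        unique = {g for g in grids.values()}
        if len(unique) > 1:
            raise ValueError("all dose volumes must share one grid")
        for name, d in self.doses.items():
            if d.unit != "Gy":
                raise ValueError(f"dose volume {name!r} must have unit Gy")
        if self.doses and self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0 when doses are present")


# ---------------------------------------------------------------------------
# CT series


def _new_file_dataset(sop_class_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    return ds


def write_ct_series(volume: ScalarVolume, directory: str | Path,
                    patient_id: str = "SYN000") -> list[Path]:
    """Write an HU volume as one axial CT series (one file per slice)."""
    if volume.unit != "HU":
        raise ValueError("write_ct_series expects an HU volume")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = volume.grid
    series_uid = generate_uid()
    study_uid = generate_uid()
    for_uid = generate_uid()
    paths = []
    stored = np.round(volume.values + 1024.0).astype(np.uint16)
    for k in range(grid.shape[2]):
        ds = _new_file_dataset(_CT_STORAGE)
        ds.Modality = "CT"
        ds.PatientID = patient_id
        ds.PatientName = patient_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [grid.origin[0], grid.origin[1],
                                   grid.origin[2] + k * grid.spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # row, column
        ds.SliceThickness = grid.spacing[2]
        ds.Rows = grid.shape[1]
        ds.Columns = grid.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_ct_series(directory: str | Path) -> ScalarVolume:
    """Read a single axial CT series from *directory* into an HU volume.

    Slices are sorted by z position regardless of file order; mixed series or
    non-uniform slice spacing beyond 1% raise ValueError.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    slices = []
    for p in files:
        ds = pydicom.dcmread(p)
        if getattr(ds, "Modality", None) == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    series_uids = {ds.SeriesInstanceUID for ds in slices}
    if len(series_uids) > 1:
        raise ValueError(f"mixed series in {directory}: {sorted(series_uids)}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) < 2:
        raise ValueError("CT series needs at least 2 slices")
    dzs = np.diff(zs)
    dz = float(np.median(dzs))
    if dz <= 0 or np.any(np.abs(dzs - dz) > 0.01 * dz):
        raise ValueError(
            f"non-uniform slice spacing (deviation beyond 1% of {dz:.3f} mm); "
            "a slice may be missing"
        )
    first = slices[0]
    ny, nx = int(first.Rows), int(first.Columns)
    dy, dx = (float(v) for v in first.PixelSpacing)
    ox, oy = (float(v) for v in first.ImagePositionPatient[:2])
    grid = VoxelGrid(origin=(ox, oy, zs[0]), spacing=(dx, dy, dz),
                     shape=(nx, ny, len(slices)))
    values = np.empty(grid.shape, dtype=np.float64)
    for k, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        values[:, :, k] = ds.pixel_array.astype(np.float64).T * slope + intercept
    return ScalarVolume(grid, values, "HU")


# ---------------------------------------------------------------------------
# RTSTRUCT


def write_rtstruct(structures: StructureSet, path: str | Path,
                   frame_of_reference_uid: str | None = None) -> Path:
    """Write a structure set as a minimal RTSTRUCT file."""
    path = Path(path)
    ds = _new_file_dataset(_RTSTRUCT_STORAGE)
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "gasdose"
    for_uid = frame_of_reference_uid or generate_uid()
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, structure in enumerate(structures, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = structure.name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for z, verts in structure.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = verts.shape[0]
            data = np.column_stack([verts, np.full(verts.shape[0], z)])
            c.ContourData = [float(v) for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtstruct(path: str | Path) -> StructureSet:
    """Read an RTSTRUCT file; ROIs without contour data are omitted with a
    logged warning."""
    ds = pydicom.dcmread(path)
    names = {int(roi.ROINumber): str(roi.ROIName)
             for roi in getattr(ds, "StructureSetROISequence", [])}
    out = StructureSet()
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(rc.ReferencedROINumber),
                         f"ROI{int(rc.ReferencedROINumber)}")
        contour_seq = getattr(rc, "ContourSequence", None)
        if not contour_seq:
            logger.warning("ROI %r has no contour data; omitted", name)
            continue
        contours = []
        for c in contour_seq:
            pts = np.asarray(c.ContourData, dtype=np.float64).reshape(-1, 3)
            contours.append((float(pts[0, 2]), pts[:, :2]))
        out.add(Structure(name, contours))
    return out


# ---------------------------------------------------------------------------
# RTDOSE


def write_rtdose(dose: ScalarVolume, path: str | Path,
                 scaling: float = 1e-3) -> Path:
    """Write a dose volume as a grid-scaled RTDOSE (stored = round(Gy/scaling))."""
    if dose.unit != "Gy":
        raise ValueError("write_rtdose expects a Gy volume")
    path = Path(path)
    grid = dose.grid
    stored = np.round(dose.values / scaling)
    if stored.max() > 2**32 - 1:
        raise ValueError("dose grid scaling too small for 32-bit storage")
    ds = _new_file_dataset(_RTDOSE_STORAGE)
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImagePositionPatient = list(grid.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.GridFrameOffsetVector = [k * grid.spacing[2] for k in range(grid.shape[2])]
    ds.NumberOfFrames = grid.shape[2]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(
        stored.astype(np.uint32).transpose(2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtdose(path: str | Path) -> ScalarVolume:
    """Read a grid-scaled RTDOSE file into a Gy volume."""
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise ValueError("RTDOSE file is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    frames = ds.pixel_array.astype(np.float64)  # (nz, ny, nx)
    if frames.ndim == 2:
        frames = frames[None]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    grid = VoxelGrid(origin=(ox, oy, oz + offsets[0]), spacing=(dx, dy, dz),
                     shape=(frames.shape[2], frames.shape[1], frames.shape[0]))
    return ScalarVolume(grid, frames.transpose(2, 1, 0) * scaling, "Gy")


# ---------------------------------------------------------------------------
# calibration table


def read_calibration_table(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column (HU, RED) text table; returns points sorted by HU.

    Commas, semicolons and whitespace are accepted as delimiters; a single
    non-numeric header line is skipped.  Duplicate HU values raise ValueError;
    RED non-monotone in HU only warns (the curve is kept).
    """
    points = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip().replace(",", " ").replace(";", " ")
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            hu, red = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            continue  # header or malformed line
        points.append((hu, red))
    if len(points) < 2:
        raise ValueError(f"calibration table {path} has fewer than 2 points")
    hus = [p[0] for p in points]
    if len(set(hus)) != len(hus):
        raise ValueError(f"calibration table {path} has duplicate HU values")
    points.sort(key=lambda p: p[0])
    reds = np.array([p[1] for p in points])
    if np.any(np.diff(reds) < 0):
        warnings.warn("calibration table RED is not monotone in HU", stacklevel=2)
    return points


# ---------------------------------------------------------------------------
# internal case bundle (single compressed file)


def save_case(case: PatientCase, path: str | Path) -> Path:
    """Save a full PatientCase into one compressed ``.npz``-format bundle."""
    path = Path(path)
    header = {
        "prescription_dose": case.prescription_dose,
        "ct_grid": {"origin": case.ct.grid.origin,
                    "spacing": case.ct.grid.spacing,
                    "shape": case.ct.grid.shape},
        "dose_names": list(case.doses),
        "structures": [
            {"name": s.name,
             "contours": [{"z": z, "xy": verts.tolist()} for z, verts in s.contours]}
            for s in case.structures
        ],
    }
    arrays = {"ct": case.ct.values,
              "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for name, d in case.doses.items():
        arrays[f"dose_{name}"] = d.values
        arrays["dose_grid"] = np.array(d.grid.origin + d.grid.spacing
                                       + tuple(float(n) for n in d.grid.shape))
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)
    return path


def load_case(path: str | Path) -> PatientCase:
    """Load a PatientCase bundle written by :func:`save_case`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        g = header["ct_grid"]
        ct_grid = VoxelGrid(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["shape"]))
        ct = ScalarVolume(ct_grid, data["ct"], "HU")
        structures = StructureSet(
            Structure(s["name"],
                      [(c["z"], np.asarray(c["xy"])) for c in s["contours"]])
            for s in header["structures"]
        )
        doses = {}
        if header["dose_names"]:
            dg = data["dose_grid"]
            dose_grid = VoxelGrid(tuple(dg[:3]), tuple(dg[3:6]),
                                  tuple(int(n) for n in dg[6:9]))
            for name in header["dose_names"]:
                doses[name] = ScalarVolume(dose_grid, data[f"dose_{name}"], "Gy")
    return PatientCase(ct=ct, structures=structures, doses=doses,
                       prescription_dose=header["prescription_dose"])
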