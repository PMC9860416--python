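"""Standard-format I/O: NRRD/MetaImage volumes, DICOM RT Dose, scenario bundles.

Index-order note: the package stores arrays as ``(x, y, z)``; SimpleITK and
DICOM pixel data are ``(z, y, x)``, so every read/write transposes.  Dose is
cGy everywhere inside the package; DICOM RT Dose in Gy is converted at the
boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grid import (
    GeometryError,
    GridGeometry,
    ImageGrid,
    RigidTransform,
    StructureSet,
    VectorField,
)
from .phantoms import FractionData, ScenarioBundle

__all__ = [
    "read_volume",
    "write_volume",
    "read_rtdose",
    "write_rtdose",
    "save_bundle",
    "load_bundle",
]

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_SUPPORTED_SUFFIXES = (".nrrd", ".nhdr", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise GeometryError(
            f"unsupported volume dialect {path.suffix!r}; expected one of "
            f"{_SUPPORTED_SUFFIXES} (NRRD or MetaImage)"
        )


def write_volume(obj: ImageGrid | VectorField, path: str | Path) -> None:
    """Write a scalar grid or displacement field as NRRD/MetaImage (mm units)."""
    path = Path(path)
    _check_suffix(path)
    if isinstance(obj, VectorField):
        arr = np.transpose(obj.displacements, (2, 1, 0, 3))
        img = sitk.GetImageFromArray(arr, isVector=True)
    elif isinstance(obj, ImageGrid):
        img = sitk.GetImageFromArray(obj.values.T)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img.SetOrigin(tuple(obj.origin))
    img.SetSpacing(tuple(obj.spacing))
    if obj.frame_id:
        img.SetMetaData("frame_id", obj.frame_id)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path: str | Path) -> ImageGrid | VectorField:
    """Read NRRD/MetaImage; 1-component volumes become :class:`ImageGrid`,
    3-component volumes become :class:`VectorField` (mm displacements)."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise GeometryError(
            f"{path.name}: expected a 3-D volume, got {img.GetDimension()}-D"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-9):
        raise GeometryError(
            f"{path.name}: oblique direction cosines are unsupported "
            "(axis-aligned grid model)"
        )
    origin = tuple(float(v) for v in img.GetOrigin())
    spacing = tuple(float(v) for v in img.GetSpacing())
    frame_id = img.GetMetaData("frame_id") if img.HasMetaDataKey("frame_id") else ""
    ncomp = img.GetNumberOfComponentsPerPixel()
    arr = sitk.GetArrayFromImage(img)
    if ncomp == 1:
        return ImageGrid(arr.T.astype(np.float64), origin, spacing, frame_id)
    if ncomp == 3:
        disp = np.transpose(arr, (2, 1, 0, 3)).astype(np.float64)
        return VectorField(disp, origin, spacing, frame_id)
    raise GeometryError(f"{path.name}: {ncomp}-component volumes are unsupported")


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

def write_rtdose(grid: ImageGrid, path: str | Path) -> None:
    """Write a dose grid (cGy) as a DICOM RT Dose object (Gy, 32-bit scaled)."""
    path = Path(path)
    dose_gy = grid.values / 100.0
    max_gy = float(dose_gy.max())
    scaling = max_gy / (2 ** 32 - 1) if max_gy > 0 else 1e-8
    scaling = max(scaling, 1e-12)
    stored = np.round(dose_gy / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.FrameIncrementPointer = (0x3004, 0x000C)
    ds.PixelData = np.transpose(stored, (2, 1, 0)).tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_rtdose(path: str | Path) -> ImageGrid:
    """Read a DICOM RT Dose object into a cGy :class:`ImageGrid`."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE" or getattr(ds, "SOPClassUID", "") != _RTDOSE_SOP_CLASS:
        raise GeometryError(f"{Path(path).name}: not a DICOM RT Dose object")
    if "DoseGridScaling" not in ds:
        raise GeometryError("RT Dose is missing DoseGridScaling")
    if "GridFrameOffsetVector" not in ds:
        raise GeometryError("RT Dose is missing GridFrameOffsetVector")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size < 2:
        raise GeometryError("RT Dose needs at least two frames")
    steps = np.diff(offsets)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise GeometryError(
            "non-uniform GridFrameOffsetVector is unsupported (uniform-spacing model)"
        )
    stored = ds.pixel_array  # (frames, rows, cols) = (z, y, x)
    dose_gy = stored.astype(np.float64) * float(ds.DoseGridScaling)
    if getattr(ds, "DoseUnits", "GY").upper() == "GY":
        dose = dose_gy * 100.0
    else:
        dose = dose_gy
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), float(steps[0]))
    return ImageGrid(np.transpose(dose, (2, 1, 0)), origin, spacing, "")


# ---------------------------------------------------------------------------
# Scenario bundle (de)serialization
# ---------------------------------------------------------------------------

_MANIFEST_SCHEMA = 1


def _write_structures(structs: StructureSet, stem: Path, prefix: str, manifest_entry: dict) -> None:
    names = []
    for name, mask in structs.masks.items():
        fname = f"{prefix}_struct_{name}.nrrd"
        g = structs.geometry
        img = sitk.GetImageFromArray(mask.astype(np.uint8).T)
        img.SetOrigin(tuple(g.origin))
        img.SetSpacing(tuple(g.spacing))
        sitk.WriteImage(img, str(stem / fname), useCompression=False)
        names.append(name)
    manifest_entry["structures"] = names
    manifest_entry["priorities"] = dict(structs.priorities)


def _read_structures(stem: Path, prefix: str, entry: dict, geom: GridGeometry) -> StructureSet:
    masks = {}
    for name in entry["structures"]:
        img = sitk.ReadImage(str(stem / f"{prefix}_struct_{name}.nrrd"))
        masks[name] = sitk.GetArrayFromImage(img).T.astype(bool)
    return StructureSet(masks, geom, {k: int(v) for k, v in entry["priorities"].items()})


def save_bundle(bundle: ScenarioBundle, directory: str | Path) -> None:
    """Serialize a scenario to a directory of NRRD volumes plus a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema": _MANIFEST_SCHEMA,
        "kind": bundle.kind,
        "seed": bundle.seed,
        "rx_per_fraction_cgy": bundle.rx_per_fraction,
        "swapped_structures": list(bundle.swapped_structures),
        "reference": {"frame_id": bundle.reference_ct.frame_id},
        "fractions": [],
    }
    write_volume(bundle.reference_ct, d / "reference_ct.nrrd")
    _write_structures(bundle.reference_structures, d, "reference", manifest["reference"])
    for i, f in enumerate(bundle.fractions, start=1):
        entry: dict = {
            "frame_id": f.frame_id,
            "rigid": f.rigid.to_list(),
            "target_hour": f.target_hour,
        }
        write_volume(f.session_ct, d / f"fx{i}_ct.nrrd")
        write_volume(f.session_dose, d / f"fx{i}_dose.nrrd")
        write_volume(f.dvf, d / f"fx{i}_dvf.nrrd")
        _write_structures(f.session_structures, d, f"fx{i}", entry)
        manifest["fractions"].append(entry)
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(directory: str | Path) -> ScenarioBundle:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("schema") != _MANIFEST_SCHEMA:
        raise GeometryError(
            f"unsupported bundle schema {manifest.get('schema')!r} (expected {_MANIFEST_SCHEMA})"
        )
    ref_ct = read_volume(d / "reference_ct.nrrd")
    assert isinstance(ref_ct, ImageGrid)
    ref_structs = _read_structures(d, "reference", manifest["reference"], ref_ct.geometry)
    fractions = []
    for i, entry in enumerate(manifest["fractions"], start=1):
        ct = read_volume(d / f"fx{i}_ct.nrrd")
        dose = read_volume(d / f"fx{i}_dose.nrrd")
        dvf = read_volume(d / f"fx{i}_dvf.nrrd")
        assert isinstance(ct, ImageGrid) and isinstance(dose, ImageGrid)
        assert isinstance(dvf, VectorField)
        structs = _read_structures(d, f"fx{i}", entry, ct.geometry)
        fractions.append(
            FractionData(
                entry["frame_id"], ct, structs, dose,
                RigidTransform.from_list(entry["rigid"]), dvf,
                entry.get("target_hour"),
            )
        )
    return ScenarioBundle(
        manifest["kind"], int(manifest["seed"]), float(manifest["rx_per_fraction_cgy"]),
        ref_ct, ref_structs, fractions, tuple(manifest["swapped_structures"]),
    )
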