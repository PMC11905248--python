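"""Readers/writers for the formats the workflow touches.

NIfTI is the working format (image, dose, masks, displacement fields);
DICOM RT Dose and RT Structure Set readers cover clinical exports.  Only
axis-aligned geometry is supported — an oblique affine raises
:class:`UnsupportedOrientationError` rather than being silently resampled.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from matplotlib.path import Path as MplPath

from .core import (
    DisplacementField,
    GridDescriptor,
    ImageVolume,
    StructureSet,
    sample_volume,
)
from .phantom import CaseBundle

_ORIENT_TOL = 1e-3


class UnsupportedOrientationError(ValueError):
    """The volume is not axis-aligned in the supported (+x, +y, +z) sense."""


class FormatError(ValueError):
    """A DICOM object is missing attributes the reader requires."""


# ---------------------------------------------------------------------------
# NIfTI


def _grid_from_affine(affine: np.ndarray, shape) -> GridDescriptor:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > _ORIENT_TOL or np.any(np.diag(rot) <= 0):
        raise UnsupportedOrientationError(
            "only axis-aligned volumes with positive spacing are supported; "
            f"got affine rotation block {rot.tolist()}"
        )
    return GridDescriptor(tuple(shape[:3]), tuple(np.diag(rot)), tuple(affine[:3, 3]))


def _affine_from_grid(grid: GridDescriptor) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return ImageVolume(data, grid)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), _affine_from_grid(vol.grid))
    nib.save(img, str(path))


def read_field(path: str | Path) -> DisplacementField:
    """Displacement field from a 4D NIfTI (last axis = vector component, mm)."""
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(f"expected a 4D (x,y,z,3) field, got shape {data.shape}")
    return DisplacementField(np.moveaxis(data, 3, 0), grid)


def write_field(field: DisplacementField, path: str | Path) -> None:
    data = np.moveaxis(field.vectors_mm, 0, 3)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine_from_grid(field.grid))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM RT


def read_rtdose(path: str | Path) -> ImageVolume:
    """RT Dose -> Gy volume.  Requires DoseGridScaling and a uniform
    GridFrameOffsetVector; pixel data are stored (frame, row, col) =
    (z, y, x) and transposed to this package's (x, y, z) order."""
    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "DoseGridScaling"):
        raise FormatError("RT Dose object lacks DoseGridScaling")
    iop = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    if np.abs(np.asarray(iop, dtype=float) - [1, 0, 0, 0, 1, 0]).max() > _ORIENT_TOL:
        raise UnsupportedOrientationError(f"non-axis-aligned RT Dose orientation {iop}")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if len(dz) == 0:
        raise FormatError("RT Dose must contain more than one frame")
    if np.abs(dz - dz[0]).max() > _ORIENT_TOL or dz[0] <= 0:
        raise FormatError(f"non-uniform GridFrameOffsetVector: {offsets.tolist()}")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)  # row pitch = y, col pitch = x
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) + [0.0, 0.0, offsets[0]]
    dose = np.asarray(ds.pixel_array, dtype=np.float64) * float(ds.DoseGridScaling)
    dose = np.transpose(dose, (2, 1, 0))  # (z, y, x) -> (x, y, z)
    grid = GridDescriptor(dose.shape, (col_mm, row_mm, float(dz[0])), tuple(origin))
    return ImageVolume(dose, grid)


def read_rtstruct(path: str | Path, target_grid: GridDescriptor) -> StructureSet:
    """RT Structure Set -> binary masks on ``target_grid``.

    Planar contours are rasterized slice-by-slice with a voxel-center-in-
    polygon test; multiple contours on one slice combine with even-odd
    (XOR) semantics, so holes and multi-part structures behave as drawn.
    Contours on slices outside the grid are clipped with a warning.
    """
    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    xs = target_grid.axis_coords(0)
    ys = target_grid.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    masks: dict[str, np.ndarray] = {}
    for roi in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi.ReferencedROINumber), f"roi_{roi.ReferencedROINumber}")
        mask = np.zeros(target_grid.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.mean(pts[:, 2]))
            k = (z - target_grid.origin[2]) / target_grid.spacing[2]
            ki = int(round(k))
            if abs(k - ki) > 0.5 + _ORIENT_TOL or not (0 <= ki < target_grid.shape[2]):
                warnings.warn(
                    f"contour of '{name}' at z={z:.2f} mm lies outside the grid; clipped",
                    stacklevel=2,
                )
                continue
            inside = MplPath(pts[:, :2]).contains_points(centers)
            mask[:, :, ki] ^= inside.reshape(len(xs), len(ys))
        masks[name] = mask
    return StructureSet(masks, target_grid)


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(
    vol: ImageVolume, grid: GridDescriptor, mode: str = "linear"
) -> ImageVolume:
    """Resample onto another axis-aligned grid (trilinear or nearest).

    Target voxel centers outside the source support get 0.
    """
    if vol.grid.same_geometry(grid):
        return vol.copy()
    idx = np.meshgrid(
        *[
            (grid.axis_coords(a) - vol.grid.origin[a]) / vol.grid.spacing[a]
            for a in range(3)
        ],
        indexing="ij",
        sparse=False,
    )
    data = sample_volume(vol, np.stack(idx), mode=mode, cval=0.0, edge="constant")
    return ImageVolume(data, grid)


# ---------------------------------------------------------------------------
# case directories


def write_case(case: CaseBundle, out_dir: str | Path) -> Path:
    """Planning case -> NIfTI volumes + JSON manifest.  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.image, out / "image.nii.gz")
    write_volume(case.plan_dose, out / "plan_dose.nii.gz")
    (out / "structures").mkdir(exist_ok=True)
    for name, m in case.structures.masks.items():
        write_volume(ImageVolume(m.astype(np.float64), case.grid), out / "structures" / f"{name}.nii.gz")
    manifest = {
        "schema": "doseaccum-case-1",
        "prescription_gy": case.prescription_gy,
        "n_fractions": case.n_fractions,
        "spacing_mm": list(case.grid.spacing_mm),
        "shape": list(case.grid.shape),
        "origin_mm": list(case.grid.origin_mm),
        "axes": ["RL", "AP", "SI"],
        "structures": sorted(case.structures.names),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_case(case_dir: str | Path) -> CaseBundle:
    case_dir = Path(case_dir)
    manifest = json.loads((case_dir / "manifest.json").read_text())
    image = read_volume(case_dir / "image.nii.gz")
    dose = read_volume(case_dir / "plan_dose.nii.gz")
    masks = {
        name: read_volume(case_dir / "structures" / f"{name}.nii.gz").data >= 0.5
        for name in manifest["structures"]
    }
    return CaseBundle(
        image=image,
        structures=StructureSet(masks, image.grid),
        plan_dose=dose,
        prescription_gy=float(manifest["prescription_gy"]),
        n_fractions=int(manifest["n_fractions"]),
    )
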