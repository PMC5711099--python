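"""NIfTI and DICOM-series ingest for SUV volumes and masks."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .volumes import BinaryMask, ImageGrid, SuvVolume


def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(shape: tuple[int, ...], affine: np.ndarray) -> ImageGrid:
    rot = affine[:3, :3]
    off = np.abs(rot - np.diag(np.diag(rot))).max()
    if off > 1e-6:
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI grids are supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine must have positive diagonal spacings")
    return ImageGrid(tuple(shape[:3]), tuple(spacing), tuple(affine[:3, 3]))


def save_suv_nifti(vol: SuvVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.grid)), path)


def load_suv_nifti(path: str | os.PathLike) -> SuvVolume:
    img = nib.load(path)
    grid = _grid_from_affine(img.shape, img.affine)
    return SuvVolume(grid, np.asarray(img.dataobj, dtype=float))


def save_mask_nifti(mask: BinaryMask, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(mask.member.astype(np.uint8), _affine(mask.grid)), path)


def load_mask_nifti(path: str | os.PathLike) -> BinaryMask:
    img = nib.load(path)
    grid = _grid_from_affine(img.shape, img.affine)
    return BinaryMask(grid, np.asarray(img.dataobj) > 0.5)


def load_dicom_series(paths: list[str | os.PathLike]) -> SuvVolume:
    """Read an axis-aligned DICOM image series as an SUV volume.

    Slice geometry comes from ImagePositionPatient / PixelSpacing; slices are
    sorted by their z position. Rescale slope/intercept are applied; the
    stored values are assumed to already be in SUV units.
    """
    import pydicom

    slices = sorted(
        (pydicom.dcmread(str(p)) for p in paths),
        key=lambda d: float(d.ImagePositionPatient[2]),
    )
    first = slices[0]
    ny, nx = int(first.Rows), int(first.Columns)
    sy, sx = (float(v) for v in first.PixelSpacing)
    zs = [float(d.ImagePositionPatient[2]) for d in slices]
    sz = zs[1] - zs[0] if len(zs) > 1 else float(getattr(first, "SliceThickness", 1.0))
    grid = ImageGrid(
        (nx, ny, len(slices)),
        (sx, sy, sz),
        (
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            zs[0],
        ),
    )
    vals = np.empty(grid.shape, dtype=float)
    for k, ds in enumerate(slices):
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        vals[:, :, k] = (arr * slope + inter).T
    return SuvVolume(grid, np.maximum(vals, 0.0))
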