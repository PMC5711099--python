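"""Grids, SUV volumes, binary masks, rigid transforms, and resampling.

Coordinate conventions
----------------------
All positions are in patient millimetres. Grids are axis-aligned; voxel
indices are 0-based and the center of voxel ``(i, j, k)`` sits at
``origin + index * spacing``. A voxel's spatial extent is the half-open box
``[center - spacing/2, center + spacing/2)``, which makes rasterization and
contour round-trips unambiguous.

SUV (standardized uptake value) is treated as the input intensity unit;
conversion from raw activity (decay, weight normalization) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned 3-D sampling grid in patient millimetres.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel spacing in mm along (x, y, z); all strictly positive.
    origin : tuple of float
        Patient-space position (mm) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be three positives, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Voxel indices (n, 3) -> voxel-center coordinates in mm."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + ijk * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Patient mm (n, 3) -> continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of voxel-center coordinates (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a]) for a in range(3)
        )

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer box (mm) spanned by the voxel extents: (min corner, max corner)."""
        o = np.asarray(self.origin)
        s = np.asarray(self.spacing)
        d = np.asarray(self.dims)
        return o - s / 2.0, o + (d - 1) * s + s / 2.0


def voxel_volume_ml(grid: ImageGrid) -> float:
    """Volume of one voxel in millilitres (product of spacings / 1000)."""
    return grid.voxel_volume_ml


@dataclass
class SuvVolume:
    """Scalar SUV field sampled on an :class:`ImageGrid`.

    ``values`` is indexed ``[i, j, k]`` matching the grid's (x, y, z) axes.
    All values must be finite and non-negative (SUV is a non-negative unit).
    """

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")


@dataclass
class BinaryMask:
    """Voxel membership set on an :class:`ImageGrid`."""

    grid: ImageGrid
    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.member.shape} != grid dims {self.grid.shape}"
            )

    @property
    def volume_ml(self) -> float:
        return mask_volume_ml(self)


def mask_volume_ml(mask: BinaryMask) -> float:
    """Volume of a mask in ml: true-voxel count times the voxel volume."""
    return int(mask.member.sum()) * mask.grid.voxel_volume_ml


@dataclass(frozen=True)
class RigidTransform:
    """Rigid body transform x -> R x + t in patient millimetres.

    ``rotation`` must be orthonormal with determinant +1; the identity is the
    default. Registration *estimation* is out of scope — transforms are
    inputs, typically exported from a registration workstation.
    """

    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(
            self.translation, 0.0
        )


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned analysis box in patient mm.

    Plays the physician's role of restricting segmentation to the tumor
    region and excluding physiological uptake (e.g. bladder).
    """

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("corners must be mm triples")
        if not np.all(lo < hi):
            raise ValueError(f"RoiBox min {tuple(lo)} must be < max {tuple(hi)}")
        object.__setattr__(self, "min_corner", tuple(lo))
        object.__setattr__(self, "max_corner", tuple(hi))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership (inclusive bounds) for (n, 3) mm points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.min_corner)
        hi = np.asarray(self.max_corner)
        return np.all((p >= lo) & (p <= hi), axis=-1)

    def index_slices(self, grid: ImageGrid) -> tuple[slice, slice, slice]:
        """Slices of grid voxels whose centers fall inside the box.

        Raises ``ValueError`` if the box misses the grid entirely.
        """
        lo = np.asarray(self.min_corner)
        hi = np.asarray(self.max_corner)
        o = np.asarray(grid.origin)
        s = np.asarray(grid.spacing)
        first = np.maximum(0, np.ceil((lo - o) / s - 1e-9).astype(int))
        last = np.minimum(np.asarray(grid.dims) - 1, np.floor((hi - o) / s + 1e-9).astype(int))
        if np.any(first > last):
            raise ValueError("RoiBox does not intersect the grid")
        return tuple(slice(int(a), int(b) + 1) for a, b in zip(first, last))

    def grid_mask(self, grid: ImageGrid) -> np.ndarray:
        """Boolean array over the grid: voxel centers inside the box."""
        out = np.zeros(grid.shape, dtype=bool)
        out[self.index_slices(grid)] = True
        return out


def _target_source_indices(
    source: ImageGrid, target: ImageGrid, xf: RigidTransform
) -> np.ndarray:
    """Continuous source-grid indices of every target voxel center.

    ``xf`` maps target patient coordinates into source patient coordinates.
    Returns an array of shape (3, nx, ny, nz) for ``ndimage.map_coordinates``.
    """
    cx, cy, cz = target.voxel_centers()
    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    src_pts = xf.apply(pts)
    idx = source.world_to_index(src_pts)
    return idx.T.reshape(3, *target.shape)


def resample_suv(
    vol: SuvVolume, target: ImageGrid, xf: RigidTransform | None = None
) -> SuvVolume:
    """Resample an SUV volume onto a target grid by trilinear interpolation.

    Mirrors the clinical workstation step of resampling PET onto the
    planning-CT voxel lattice. Points outside the source extent read 0
    (background air). With the identity transform and ``target`` equal to
    the source grid this is an exact identity.
    """
    xf = xf or RigidTransform.identity()
    if target.shape == vol.grid.shape and target == vol.grid and xf.is_identity:
        return SuvVolume(target, vol.values.copy())
    coords = _target_source_indices(vol.grid, target, xf)
    out = ndimage.map_coordinates(
        vol.values, coords, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return SuvVolume(target, np.maximum(out, 0.0))


def resample_mask(
    mask: BinaryMask, target: ImageGrid, xf: RigidTransform | None = None
) -> BinaryMask:
    """Resample a mask onto a target grid by nearest-neighbor lookup."""
    xf = xf or RigidTransform.identity()
    if target.shape == mask.grid.shape and target == mask.grid and xf.is_identity:
        return BinaryMask(target, mask.member.copy())
    coords = _target_source_indices(mask.grid, target, xf)
    out = ndimage.map_coordinates(
        mask.member.astype(np.uint8), coords, order=0, mode="constant", cval=0
    )
    return BinaryMask(target, out.astype(bool))


def suv_stats(vol: SuvVolume, mask: BinaryMask) -> tuple[float, float]:
    """SUVmax and SUVmean of a volume over a mask.

    Raises ``ValueError`` for an empty mask (the statistics are undefined)
    or for a grid mismatch.
    """
    if mask.grid != vol.grid:
        raise ValueError("mask and volume must share a grid")
    sel = vol.values[mask.member]
    if sel.size == 0:
        raise ValueError("SUV statistics are undefined on an empty mask")
    return float(sel.max()), float(sel.mean())
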