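"""Mask <-> planar-contour conversion and DICOM RT Structure Set I/O.

Two boundary dialects are modeled, matching the two behaviors clinical
software exhibits when a voxel mask is exported as closed planar contours:

* ``voxel_edge`` — the polygon follows the outer edges of the boundary
  voxels (a staircase through voxel corners), so re-rasterizing it with a
  center-inside rule on the source grid reproduces the mask exactly;
* ``voxel_center`` — the polygon passes through the centers of the boundary
  voxels, so the drawn contour sits half a voxel inside the voxel extent.

Re-rasterization likewise follows one of two rules: ``center_inside``
(voxel kept iff its center is inside or on the polygon) or ``any_overlap``
(kept iff its in-plane box touches the polygon). Mixing dialect and rule
across an export/import pair is the mechanism by which DICOM-RT transfer
between workstations systematically shrinks or expands a tumor volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .volumes import BinaryMask, ImageGrid, mask_volume_ml

VOXEL_EDGE = "voxel_edge"
VOXEL_CENTER = "voxel_center"
_DIALECTS = (VOXEL_EDGE, VOXEL_CENTER)

CENTER_INSIDE = "center_inside"
ANY_OVERLAP = "any_overlap"
_RULES = (CENTER_INSIDE, ANY_OVERLAP)


@dataclass
class PlanarContour:
    """Closed planar polygon on one axial slice (closure implicit)."""

    z: float
    points: np.ndarray  # (n, 2) x,y in mm; first point not repeated

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 3:
            raise ValueError("a planar contour needs at least 3 points")
        if abs(self.area) == 0:
            raise ValueError("contour encloses zero area")

    @property
    def area(self) -> float:
        """Signed shoelace area (mm^2); positive for counterclockwise."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ContourSet:
    """Stack of planar contours with its boundary-dialect tag."""

    name: str
    contours: list[PlanarContour]
    dialect: str
    frame_of_reference: str = "1.2.826.0.1.3680043.8.498.1"
    n_skipped: int = 0  # degenerate slices (< 3 distinct centers) dropped

    def __post_init__(self) -> None:
        if self.dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")


# ---------------------------------------------------------------------------
# mask -> contours
# ---------------------------------------------------------------------------

def _slice_component_loops(comp: np.ndarray) -> list[tuple[list[tuple[float, float]], list[tuple[int, int]]]]:
    """Trace the directed boundary loops of one 2-D pixel component.

    Returns, per loop, the corner-point cycle (in half-integer index
    coordinates) and the cyclic sequence of owning pixels. Edges are
    oriented with the component interior on the left, so outer loops run
    counterclockwise.
    """
    edges: dict[tuple[float, float], list[tuple[tuple[float, float], tuple[int, int]]]] = {}

    def add(p0, p1, owner):
        edges.setdefault(p0, []).append((p1, owner))

    nx, ny = comp.shape
    idx = np.argwhere(comp)
    for i, j in idx:
        i, j = int(i), int(j)
        if j == 0 or not comp[i, j - 1]:
            add((i - 0.5, j - 0.5), (i + 0.5, j - 0.5), (i, j))
        if i == nx - 1 or not comp[i + 1, j]:
            add((i + 0.5, j - 0.5), (i + 0.5, j + 0.5), (i, j))
        if j == ny - 1 or not comp[i, j + 1]:
            add((i + 0.5, j + 0.5), (i - 0.5, j + 0.5), (i, j))
        if i == 0 or not comp[i - 1, j]:
            add((i - 0.5, j + 0.5), (i - 0.5, j - 0.5), (i, j))

    for k in edges:
        edges[k].sort()  # deterministic pinch-corner tie-break

    loops = []
    while edges:
        start = min(edges)
        point = start
        loop_pts: list[tuple[float, float]] = []
        owners: list[tuple[int, int]] = []
        prev_dir = None
        while True:
            cands = edges[point]
            if len(cands) == 1 or prev_dir is None:
                choice = 0
            else:
                # pinch corner: take the sharpest left turn (max CCW cross
                # product with the incoming direction) to stay on one lobe
                crosses = []
                for nxt, _ in cands:
                    d = (nxt[0] - point[0], nxt[1] - point[1])
                    crosses.append(prev_dir[0] * d[1] - prev_dir[1] * d[0])
                choice = int(np.argmax(crosses))
            nxt, owner = cands.pop(choice)
            if not cands:
                del edges[point]
            loop_pts.append(point)
            owners.append(owner)
            prev_dir = (nxt[0] - point[0], nxt[1] - point[1])
            point = nxt
            if point == start:
                break
        loops.append((loop_pts, owners))
    return loops


def _simplify_collinear(points: np.ndarray) -> np.ndarray:
    """Drop vertices collinear with their cyclic neighbors."""
    keep = []
    n = len(points)
    for i in range(n):
        a, b, c = points[i - 1], points[i], points[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        if abs(cross) > 1e-12:
            keep.append(points[i])
    return np.asarray(keep)


def _dedupe_cycle(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for p in points:
        if not out or p != out[-1]:
            out.append(p)
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    return out


def mask_to_contours(
    mask: BinaryMask, dialect: str = VOXEL_EDGE, name: str = "MTV"
) -> ContourSet:
    """Convert a mask to per-slice closed polygons under a boundary dialect.

    Each in-plane 4-connected component contributes its outer boundary
    (holes are dropped). Under ``voxel_center`` a component whose boundary
    has fewer than 3 distinct voxel centers (single voxels, thin lines) is
    degenerate: it is skipped and counted in ``n_skipped``.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not mask.member.any():
        raise ValueError("cannot contour an empty mask")
    from scipy import ndimage

    grid = mask.grid
    ox, oy, oz = grid.origin
    sx, sy, sz = grid.spacing
    contours: list[PlanarContour] = []
    n_skipped = 0
    for k in range(grid.dims[2]):
        sl = mask.member[:, :, k]
        if not sl.any():
            continue
        z = oz + k * sz
        labels, ncomp = ndimage.label(sl)  # 4-connected in-plane
        for c in range(1, ncomp + 1):
            comp = labels == c
            loops = _slice_component_loops(comp)
            # outer boundary: the loop with the largest enclosed area
            areas = [abs(_shoelace(pts)) for pts, _ in loops]
            pts, owners = loops[int(np.argmax(areas))]
            if dialect == VOXEL_EDGE:
                poly = _simplify_collinear(np.asarray(pts, dtype=float))
                xy = np.column_stack([ox + poly[:, 0] * sx, oy + poly[:, 1] * sy])
                contours.append(PlanarContour(z, xy))
            else:
                centers = _dedupe_cycle(owners)
                arr = np.asarray(centers, dtype=float)
                if len(np.unique(arr, axis=0)) < 3 or abs(_shoelace(arr)) == 0:
                    n_skipped += 1
                    continue
                arr = _simplify_collinear(arr)
                if len(arr) < 3 or abs(_shoelace(arr)) == 0:
                    n_skipped += 1
                    continue
                xy = np.column_stack([ox + arr[:, 0] * sx, oy + arr[:, 1] * sy])
                contours.append(PlanarContour(z, xy))
    if not contours:
        raise ValueError("mask produced no representable contours under this dialect")
    return ContourSet(name, contours, dialect, n_skipped=n_skipped)


def _shoelace(points) -> float:
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# contours -> mask
# ---------------------------------------------------------------------------

def _polygonal_part(points: np.ndarray):
    """Shapely polygon for a point cycle; self-touching spurs are resolved
    to the valid polygonal part (zero-width excursions are dropped)."""
    poly = ShapelyPolygon(points)
    if not poly.is_valid:
        fixed = shapely.make_valid(poly)
        polys = [
            g
            for g in getattr(fixed, "geoms", [fixed])
            if isinstance(g, ShapelyPolygon)
        ]
        if not polys:
            return None
        poly = unary_union(polys)
    return poly


def contours_to_mask(
    cs: ContourSet, grid: ImageGrid, rule: str = CENTER_INSIDE
) -> BinaryMask:
    """Rasterize a contour set onto a grid under a rasterization rule.

    ``center_inside``: a voxel is kept iff its center lies inside the
    polygon or on its boundary. ``any_overlap``: kept iff the voxel's
    in-plane box intersects the polygon interior or boundary. Contour z
    planes must coincide with grid slice planes (1e-6 mm).
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rasterization rule {rule!r}")
    if not cs.contours:
        raise ValueError("empty contour set")
    ox, oy, oz = grid.origin
    sx, sy, sz = grid.spacing
    member = np.zeros(grid.shape, dtype=bool)
    cx = ox + sx * np.arange(grid.dims[0])
    cy = oy + sy * np.arange(grid.dims[1])
    for contour in cs.contours:
        kf = (contour.z - oz) / sz
        k = int(round(kf))
        if not (0 <= k < grid.dims[2]) or abs(kf - k) * sz > 1e-6:
            raise ValueError(
                f"contour plane z={contour.z} mm does not match any grid slice"
            )
        geom = _polygonal_part(contour.points)
        if geom is None or geom.is_empty:
            continue
        minx, miny, maxx, maxy = geom.bounds
        i0 = max(0, int(np.floor((minx - ox) / sx)) - 1)
        i1 = min(grid.dims[0] - 1, int(np.ceil((maxx - ox) / sx)) + 1)
        j0 = max(0, int(np.floor((miny - oy) / sy)) - 1)
        j1 = min(grid.dims[1] - 1, int(np.ceil((maxy - oy) / sy)) + 1)
        if i0 > i1 or j0 > j1:
            continue
        if rule == CENTER_INSIDE:
            gx, gy = np.meshgrid(cx[i0 : i1 + 1], cy[j0 : j1 + 1], indexing="ij")
            pts = shapely.points(gx.ravel(), gy.ravel())
            inside = shapely.covers(geom, pts).reshape(gx.shape)
            member[i0 : i1 + 1, j0 : j1 + 1, k] |= inside
        else:
            prepared = shapely.prepared.prep(geom)
            for i in range(i0, i1 + 1):
                x0, x1 = cx[i] - sx / 2, cx[i] + sx / 2
                for j in range(j0, j1 + 1):
                    b = shapely_box(x0, cy[j] - sy / 2, x1, cy[j] + sy / 2)
                    if prepared.intersects(b):
                        member[i, j, k] = True
    return BinaryMask(grid, member)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set I/O
# ---------------------------------------------------------------------------

_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def write_rtstruct(cs: ContourSet, path, image_meta: dict | None = None) -> None:
    """Write a minimal standards-conformant RT Structure Set.

    Coordinates are serialized as decimal strings with 6 decimals (so the
    quantization error per coordinate is at most 5e-7 mm). ``image_meta``
    may carry ``frame_of_reference`` and ``patient_id`` overrides; no
    vendor private tags are written.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    image_meta = image_meta or {}
    for_uid = image_meta.get("frame_of_reference", cs.frame_of_reference)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = image_meta.get("patient_name", "PHANTOM")
    ds.PatientID = image_meta.get("patient_id", "PHANTOM")
    ds.StructureSetLabel = cs.name[:16]
    ds.StructureSetDescription = f"dialect={cs.dialect}"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []

    roi = Dataset()
    roi.ROINumber = 1
    roi.ReferencedFrameOfReferenceUID = for_uid
    roi.ROIName = cs.name
    roi.ROIGenerationAlgorithm = "AUTOMATIC"
    ds.StructureSetROISequence.append(roi)

    rc = Dataset()
    rc.ReferencedROINumber = 1
    rc.ContourSequence = []
    for contour in cs.contours:
        item = Dataset()
        item.ContourGeometricType = "CLOSED_PLANAR"
        item.NumberOfContourPoints = len(contour.points)
        data = []
        for x, y in contour.points:
            data.extend([f"{x:.6f}", f"{y:.6f}", f"{contour.z:.6f}"])
        item.ContourData = data
        rc.ContourSequence.append(item)
    ds.ROIContourSequence.append(rc)

    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_rtstruct(path) -> ContourSet:
    """Read an RT Structure Set written by :func:`write_rtstruct` (or any
    single-ROI structure set with closed planar contours)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    try:
        roi = ds.StructureSetROISequence[0]
        name = str(roi.ROIName)
        for_uid = str(roi.ReferencedFrameOfReferenceUID)
        seq = ds.ROIContourSequence[0].ContourSequence
    except (AttributeError, IndexError) as exc:
        raise ValueError(f"malformed RT structure set ({path}): {exc}") from exc
    dialect = VOXEL_EDGE
    desc = str(getattr(ds, "StructureSetDescription", ""))
    if "voxel_center" in desc:
        dialect = VOXEL_CENTER
    contours = []
    for i, item in enumerate(seq):
        try:
            vals = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
        except Exception as exc:
            raise ValueError(
                f"malformed ContourData in ROIContourSequence[0].ContourSequence[{i}]"
            ) from exc
        contours.append(PlanarContour(float(vals[0, 2]), vals[:, :2]))
    return ContourSet(name, contours, dialect, frame_of_reference=for_uid)


def round_trip_volume_change(
    mask: BinaryMask,
    dialect: str,
    rule: str,
    target_grid: ImageGrid | None = None,
) -> tuple[float, float, float]:
    """Volume before and after a contour export / re-rasterization cycle.

    Returns ``(v_before_ml, v_after_ml, delta_ml)`` with
    ``delta = after - before``. The ``(voxel_edge, center_inside)`` pair on
    the source grid is an exact identity; ``(voxel_center, center_inside)``
    can only shrink, and ``(voxel_edge, any_overlap)`` can only grow.
    """
    target_grid = target_grid or mask.grid
    cs = mask_to_contours(mask, dialect)
    back = contours_to_mask(cs, target_grid, rule)
    v0 = mask_volume_ml(mask)
    v1 = mask_volume_ml(back)
    return v0, v1, v1 - v0
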