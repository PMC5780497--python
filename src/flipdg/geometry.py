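"""Cell geometries and interface-conforming triangulations.

The computational domain is a planar cell Omega split by the nuclear
membrane Gamma_M into nucleus Omega_N and cytoplasm Omega_C, with a
circular bleach region Omega_B inside the cytoplasm.  Meshes are
triangulations in which the nucleus outline is a union of element edges,
so the membrane can carry a jump (interface) condition; the bleach region
is represented by flagged elements (its boundary is not resolved because
bleaching enters the model as a volume source).

Coordinates are physical micrometres, origin at the lower-left corner of
the imaged field, y increasing upward.  Conversions to image rasters
(row 0 at the top) live in :mod:`flipdg.imaging`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point, Polygon

from .errors import GeometryError, MeshQualityError

# Region codes (also the label-image codes, with 0 = background, 3 = bleach)
BACKGROUND = 0
CYTOPLASM = 1
NUCLEUS = 2
BLEACH = 3

# Edge classes
EDGE_OUTER = 0
EDGE_INTERIOR = 1
EDGE_MEMBRANE = 2

#: Default pixel size of the imaging protocol (micrometres per pixel).
DEFAULT_PIXEL_SIZE = 0.05467326
#: Default bleach-spot diameter: a 30-pixel circle (micrometres).
DEFAULT_BLEACH_DIAMETER = 1.64
#: Default imaged field extent (micrometres).
DEFAULT_FIELD_EXTENT = (15.0, 15.0)

#: Minimum interior angle (degrees) below which a mesh is rejected.
MIN_ANGLE_DEG = 20.0


@dataclass
class CellGeometry:
    """Planar cell geometry with nucleus and cytoplasmic bleach spot.

    Outlines are closed polygons (last point implicitly joined to the
    first) in micrometres.  Invariants — nucleus strictly inside the
    cell, bleach disk strictly inside the cytoplasm — are checked at
    construction.
    """

    cell_outline: np.ndarray
    nucleus_outline: np.ndarray
    bleach_center: np.ndarray
    bleach_diameter: float = DEFAULT_BLEACH_DIAMETER
    pixel_size: float = DEFAULT_PIXEL_SIZE
    field_extent: tuple[float, float] = DEFAULT_FIELD_EXTENT

    def __post_init__(self) -> None:
        self.cell_outline = _as_closed_polygon(self.cell_outline, "cell_outline")
        self.nucleus_outline = _as_closed_polygon(self.nucleus_outline, "nucleus_outline")
        self.bleach_center = np.asarray(self.bleach_center, dtype=float).reshape(2)
        if self.bleach_diameter <= 0:
            raise GeometryError("bleach_diameter must be positive")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        cell = self.cell_polygon
        nuc = self.nucleus_polygon
        if not (nuc.within(cell) and cell.exterior.distance(nuc) > 0):
            raise GeometryError("nucleus_outline is not strictly inside cell_outline")
        disk = Point(self.bleach_center).buffer(self.bleach_diameter / 2.0, quad_segs=64)
        if not disk.within(cell):
            raise GeometryError("bleach disk is not inside the cell outline")
        if disk.distance(nuc) <= 0:
            raise GeometryError("bleach disk overlaps the nucleus (must lie in the cytoplasm)")

    @property
    def cell_polygon(self) -> Polygon:
        return Polygon(self.cell_outline)

    @property
    def nucleus_polygon(self) -> Polygon:
        return Polygon(self.nucleus_outline)

    @property
    def bleach_radius(self) -> float:
        return self.bleach_diameter / 2.0


def _as_closed_polygon(points: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError(f"{name} must be an (N, 2) array with N >= 3")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    poly = Polygon(pts)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError(f"{name} is not a valid simple polygon")
    # enforce counter-clockwise orientation
    if not poly.exterior.is_ccw:
        pts = pts[::-1]
    return pts


def _ellipse_points(center, semi_axes, n: int) -> np.ndarray:
    cx, cy = center
    a, b = semi_axes
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])


def build_synthetic_geometry(
    cell_ellipse,
    nucleus_ellipse,
    bleach_center,
    bleach_diameter: float = DEFAULT_BLEACH_DIAMETER,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    field_extent: tuple[float, float] = DEFAULT_FIELD_EXTENT,
    n_outline_points: int = 256,
) -> CellGeometry:
    """Build an elliptical cell/nucleus geometry.

    ``cell_ellipse`` and ``nucleus_ellipse`` are ``(center, semi_axes)``
    pairs in micrometres.  Containment invariants are validated by the
    :class:`CellGeometry` constructor.
    """
    cell = _ellipse_points(*cell_ellipse, n=n_outline_points)
    nucleus = _ellipse_points(*nucleus_ellipse, n=n_outline_points)
    return CellGeometry(
        cell_outline=cell,
        nucleus_outline=nucleus,
        bleach_center=np.asarray(bleach_center, dtype=float),
        bleach_diameter=bleach_diameter,
        pixel_size=pixel_size,
        field_extent=field_extent,
    )


# ---------------------------------------------------------------------------
# Geometry from label masks
# ---------------------------------------------------------------------------

def build_geometry_from_masks(label_image: np.ndarray, pixel_size: float) -> CellGeometry:
    """Extract a :class:`CellGeometry` from an integer label image.

    Label codes: 0 background, 1 cytoplasm, 2 nucleus, 3 bleach spot
    (part of the cytoplasm).  Each label must form a single connected
    component and the nucleus must lie strictly inside the cell without
    touching the image border.
    """
    from skimage import measure

    labels = np.asarray(label_image)
    if labels.ndim != 2:
        raise GeometryError("label image must be 2-D")
    if pixel_size <= 0:
        raise GeometryError("pixel_size must be positive")
    cell_mask = labels >= CYTOPLASM
    if not cell_mask.any():
        raise GeometryError("label image contains no cell (all background)")
    nuc_mask = labels == NUCLEUS
    if not nuc_mask.any():
        raise GeometryError("label image contains no nucleus (code 2)")
    bleach_mask = labels == BLEACH
    if not bleach_mask.any():
        raise GeometryError("label image contains no bleach region (code 3)")
    for name, mask in (("cell", cell_mask), ("nucleus", nuc_mask), ("bleach", bleach_mask)):
        if measure.label(mask, connectivity=2).max() != 1:
            raise GeometryError(f"{name} label is not a single connected component")
    border = np.zeros_like(nuc_mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (nuc_mask & border).any():
        raise GeometryError("nucleus label touches the image border")
    if (cell_mask & border).any():
        raise GeometryError("cell label touches the image border")

    n_rows, n_cols = labels.shape

    def to_physical(contour: np.ndarray) -> np.ndarray:
        rows, cols = contour[:, 0], contour[:, 1]
        x = (cols + 0.5) * pixel_size
        y = (n_rows - rows - 0.5) * pixel_size
        return np.column_stack([x, y])

    def largest_contour(mask: np.ndarray) -> np.ndarray:
        contours = measure.find_contours(mask.astype(float), 0.5)
        if not contours:
            raise GeometryError("could not trace a contour for a labelled region")
        return max(contours, key=len)

    cell_outline = to_physical(largest_contour(cell_mask))
    nucleus_outline = to_physical(largest_contour(nuc_mask))

    rows, cols = np.nonzero(bleach_mask)
    center = to_physical(np.array([[rows.mean(), cols.mean()]]))[0]
    area = bleach_mask.sum() * pixel_size**2
    diameter = 2.0 * np.sqrt(area / np.pi)

    return CellGeometry(
        cell_outline=cell_outline,
        nucleus_outline=nucleus_outline,
        bleach_center=center,
        bleach_diameter=diameter,
        pixel_size=pixel_size,
        field_extent=(n_cols * pixel_size, n_rows * pixel_size),
    )


def geometry_to_labels(geometry: CellGeometry, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Render a geometry as an integer label image (inverse of mask extraction)."""
    px = geometry.pixel_size
    if shape is None:
        w, h = geometry.field_extent
        shape = (int(round(h / px)), int(round(w / px)))
    n_rows, n_cols = shape
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = (cols + 0.5) * px
    y = (n_rows - rows - 0.5) * px
    labels = np.zeros(shape, dtype=np.uint8)
    in_cell = shapely.contains_xy(geometry.cell_polygon, x.ravel(), y.ravel()).reshape(shape)
    in_nuc = shapely.contains_xy(geometry.nucleus_polygon, x.ravel(), y.ravel()).reshape(shape)
    r2 = (x - geometry.bleach_center[0]) ** 2 + (y - geometry.bleach_center[1]) ** 2
    in_bleach = r2 <= geometry.bleach_radius**2
    labels[in_cell] = CYTOPLASM
    labels[in_cell & in_nuc] = NUCLEUS
    labels[in_cell & ~in_nuc & in_bleach] = BLEACH
    return labels


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Interface-conforming triangulation with region and edge labels.

    ``element_region`` is 1 (cytoplasm) or 2 (nucleus); ``edge_class``
    is 0 (outer boundary), 1 (interior) or 2 (membrane).  Every membrane
    edge separates a nucleus element from a cytoplasm element.
    """

    vertices: np.ndarray          # (V, 2) float
    triangles: np.ndarray         # (T, 3) int
    element_region: np.ndarray    # (T,) int
    element_bleach: np.ndarray    # (T,) bool
    edges: np.ndarray = field(default=None)       # (E, 2) int
    edge_tris: np.ndarray = field(default=None)   # (E, 2) int, -1 if boundary
    edge_class: np.ndarray = field(default=None)  # (E,) int
    cell_outline: np.ndarray | None = None        # resampled polygon actually meshed
    nucleus_outline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.element_region = np.asarray(self.element_region, dtype=np.int8)
        self.element_bleach = np.asarray(self.element_bleach, dtype=bool)
        if self.edges is None:
            self.edges, self.edge_tris, self.edge_class = _classify_edges(
                self.triangles, self.element_region
            )

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def element_coords(self) -> np.ndarray:
        """(T, 3, 2) vertex coordinates per element."""
        return self.vertices[self.triangles]

    @property
    def areas(self) -> np.ndarray:
        c = self.element_coords
        return 0.5 * np.abs(
            (c[:, 1, 0] - c[:, 0, 0]) * (c[:, 2, 1] - c[:, 0, 1])
            - (c[:, 2, 0] - c[:, 0, 0]) * (c[:, 1, 1] - c[:, 0, 1])
        )

    @property
    def centroids(self) -> np.ndarray:
        return self.element_coords.mean(axis=1)

    @property
    def diameters(self) -> np.ndarray:
        """Longest edge per element."""
        c = self.element_coords
        d01 = np.linalg.norm(c[:, 0] - c[:, 1], axis=1)
        d12 = np.linalg.norm(c[:, 1] - c[:, 2], axis=1)
        d20 = np.linalg.norm(c[:, 2] - c[:, 0], axis=1)
        return np.max(np.stack([d01, d12, d20]), axis=0)

    def min_angle_deg(self) -> float:
        c = self.element_coords
        angles = []
        for i in range(3):
            a = c[:, (i + 1) % 3] - c[:, i]
            b = c[:, (i + 2) % 3] - c[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    def edge_lengths(self) -> np.ndarray:
        v = self.vertices
        return np.linalg.norm(v[self.edges[:, 0]] - v[self.edges[:, 1]], axis=1)


def _classify_edges(triangles: np.ndarray, element_region: np.ndarray):
    """Build the edge table and classify outer / interior / membrane edges."""
    edge_map: dict[tuple[int, int], list[int]] = {}
    for t, tri in enumerate(triangles):
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            key = (a, b) if a < b else (b, a)
            edge_map.setdefault(key, []).append(t)
    edges, edge_tris, edge_class = [], [], []
    for (a, b), tris in edge_map.items():
        if len(tris) > 2:
            raise MeshQualityError("non-manifold edge (more than two incident triangles)")
        edges.append((a, b))
        if len(tris) == 1:
            edge_tris.append((tris[0], -1))
            edge_class.append(EDGE_OUTER)
        else:
            edge_tris.append((tris[0], tris[1]))
            if element_region[tris[0]] != element_region[tris[1]]:
                edge_class.append(EDGE_MEMBRANE)
            else:
                edge_class.append(EDGE_INTERIOR)
    return (
        np.asarray(edges, dtype=np.int64),
        np.asarray(edge_tris, dtype=np.int64),
        np.asarray(edge_class, dtype=np.int8),
    )


def _resample_closed(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polygon at uniform arclength spacing <= ``spacing``."""
    pts = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = s[-1]
    n = max(int(np.ceil(perimeter / spacing)), 12)
    si = np.linspace(0.0, perimeter, n, endpoint=False)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([x, y])


def _hex_lattice(bounds, h: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    dy = h * np.sqrt(3.0) / 2.0
    rows = []
    y = ymin
    i = 0
    while y <= ymax:
        xs = np.arange(xmin + (h / 2.0 if i % 2 else 0.0), xmax + h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        i += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def _triangulate_polygon(
    exterior: np.ndarray,
    holes: list[np.ndarray],
    h: float,
    smooth_iters: int = 3,
):
    """Triangulate a polygon (with holes) whose boundary vertices are fixed.

    Returns ``(points, triangles)`` with the boundary points (exterior
    then holes, in input order) occupying the leading rows of ``points``.
    Boundary segments are guaranteed to appear as triangulation edges;
    interior points blocking a segment's diametral circle are removed
    and the Delaunay triangulation rebuilt.
    """
    poly = Polygon(exterior, holes=[hole[::-1] for hole in holes])
    boundary_pts = np.vstack([exterior] + list(holes))
    segments = []
    offset = 0
    for loop in [exterior] + list(holes):
        n = len(loop)
        segments.extend(((offset + i, offset + (i + 1) % n) for i in range(n)))
        offset += n
    boundary_lines = poly.boundary

    interior = _hex_lattice(poly.bounds, h)
    if len(interior):
        inside = shapely.contains_xy(poly, interior[:, 0], interior[:, 1])
        interior = interior[inside]
    if len(interior):
        dist = shapely.distance(shapely.points(interior), boundary_lines)
        interior = interior[dist >= 0.6 * h]

    n_bnd = len(boundary_pts)

    def build(pts_interior):
        pts = np.vstack([boundary_pts, pts_interior]) if len(pts_interior) else boundary_pts
        tri = Delaunay(pts)
        cent = pts[tri.simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        return pts, tri.simplices[keep]

    def missing_segments(pts, tris):
        present = set()
        for t in tris:
            for i in range(3):
                a, b = int(t[i]), int(t[(i + 1) % 3])
                present.add((min(a, b), max(a, b)))
        return [s for s in segments if (min(s), max(s)) not in present]

    for _ in range(6):
        pts, tris = build(interior)
        missing = missing_segments(pts, tris)
        if not missing:
            break
        # drop interior points inside the diametral circle of missing segments
        keep = np.ones(len(interior), dtype=bool)
        for a, b in missing:
            mid = 0.5 * (boundary_pts[a] + boundary_pts[b])
            rad = 0.5 * np.linalg.norm(boundary_pts[a] - boundary_pts[b])
            d = np.linalg.norm(interior - mid, axis=1)
            keep &= d > 1.05 * rad
        if keep.all():
            raise MeshQualityError("could not recover boundary segments in Delaunay mesh")
        interior = interior[keep]
    else:
        raise MeshQualityError("boundary segment recovery did not converge")

    # Laplacian smoothing of interior points (boundary fixed), re-triangulating
    for _ in range(smooth_iters):
        if not len(interior):
            break
        neighbor_sum = np.zeros((len(pts), 2))
        neighbor_cnt = np.zeros(len(pts))
        for t in tris:
            for i in range(3):
                a, b = int(t[i]), int(t[(i + 1) % 3])
                neighbor_sum[a] += pts[b]
                neighbor_cnt[a] += 1
                neighbor_sum[b] += pts[a]
                neighbor_cnt[b] += 1
        new_interior = neighbor_sum[n_bnd:] / np.maximum(neighbor_cnt[n_bnd:, None], 1)
        inside = shapely.contains_xy(poly, new_interior[:, 0], new_interior[:, 1])
        dist = shapely.distance(shapely.points(new_interior), boundary_lines)
        ok = inside & (dist >= 0.3 * h)
        moved = interior.copy()
        moved[ok] = new_interior[ok]
        pts2, tris2 = build(moved)
        if missing_segments(pts2, tris2):
            break  # keep the previous valid mesh
        interior, pts, tris = moved, pts2, tris2

    return pts, tris


def triangulate(geometry: CellGeometry, target_edge_length: float) -> TriMesh:
    """Build an interface-conforming triangulation of a cell geometry.

    The nucleus outline is resampled at the target edge length and its
    segments are preserved as mesh edges shared by the nucleus and
    cytoplasm submeshes, so the membrane Gamma_M is exactly a subset of
    the mesh skeleton.
    """
    h = float(target_edge_length)
    if h <= 0:
        raise GeometryError("target_edge_length must be positive")
    nuc_poly = geometry.nucleus_polygon
    # crude semi-minor estimate: min distance from centroid to outline
    centroid = np.asarray(nuc_poly.centroid.coords[0])
    semi_minor = float(LineString(np.vstack([geometry.nucleus_outline,
                                             geometry.nucleus_outline[:1]])).distance(
        Point(centroid)))
    if h >= semi_minor:
        raise GeometryError(
            f"target_edge_length {h} must be smaller than the nucleus semi-minor axis "
            f"(~{semi_minor:.3g})"
        )

    cell_loop = _resample_closed(geometry.cell_outline, h)
    nuc_loop = _resample_closed(geometry.nucleus_outline, h)

    nuc_pts, nuc_tris = _triangulate_polygon(nuc_loop, [], h)
    cyt_pts, cyt_tris = _triangulate_polygon(cell_loop, [nuc_loop], h)

    # Merge vertex lists; nucleus-loop points appear verbatim in both parts.
    key_of = {}
    vertices = []

    def add_points(pts):
        idx = np.empty(len(pts), dtype=np.int64)
        for i, p in enumerate(pts):
            key = (float(p[0]), float(p[1]))
            j = key_of.get(key)
            if j is None:
                j = len(vertices)
                key_of[key] = j
                vertices.append(p)
            idx[i] = j
        return idx

    nuc_idx = add_points(nuc_pts)
    cyt_idx = add_points(cyt_pts)
    vertices = np.asarray(vertices)
    triangles = np.vstack([nuc_idx[nuc_tris], cyt_idx[cyt_tris]])
    element_region = np.concatenate([
        np.full(len(nuc_tris), NUCLEUS, dtype=np.int8),
        np.full(len(cyt_tris), CYTOPLASM, dtype=np.int8),
    ])

    # consistent CCW orientation
    coords = vertices[triangles]
    signed = 0.5 * (
        (coords[:, 1, 0] - coords[:, 0, 0]) * (coords[:, 2, 1] - coords[:, 0, 1])
        - (coords[:, 2, 0] - coords[:, 0, 0]) * (coords[:, 1, 1] - coords[:, 0, 1])
    )
    flip = signed < 0
    triangles[flip] = triangles[flip][:, ::-1]

    centroids = vertices[triangles].mean(axis=1)
    r2 = np.sum((centroids - geometry.bleach_center) ** 2, axis=1)
    element_bleach = (r2 <= geometry.bleach_radius**2) & (element_region == CYTOPLASM)

    mesh = TriMesh(
        vertices=vertices,
        triangles=triangles,
        element_region=element_region,
        element_bleach=element_bleach,
        cell_outline=cell_loop,
        nucleus_outline=nuc_loop,
    )
    min_angle = mesh.min_angle_deg()
    if min_angle < MIN_ANGLE_DEG:
        raise MeshQualityError(
            f"mesh contains a {min_angle:.1f} degree angle (< {MIN_ANGLE_DEG} degrees); "
            "adjust target_edge_length"
        )
    _check_conformity(mesh)
    return mesh


def _check_conformity(mesh: TriMesh) -> None:
    mem = mesh.edge_class == EDGE_MEMBRANE
    t = mesh.edge_tris[mem]
    if np.any(t[:, 1] < 0):
        raise MeshQualityError("membrane edge with a single incident triangle")
    if np.any(mesh.element_region[t[:, 0]] == mesh.element_region[t[:, 1]]):
        raise MeshQualityError("membrane edge between same-region triangles")
    outer = mesh.edge_class == EDGE_OUTER
    if np.any(mesh.edge_tris[outer][:, 1] >= 0):
        raise MeshQualityError("outer edge with two incident triangles")


def rectangle_mesh(
    nx: int,
    ny: int,
    width: float = 1.0,
    height: float = 1.0,
    interface_x: float | None = None,
) -> TriMesh:
    """Structured right-triangle mesh of a rectangle (verification helper).

    If ``interface_x`` is given it must coincide with a vertical grid
    line; elements left of it are labelled nucleus and the grid line
    becomes a membrane, which yields the two-slab interface benchmark.
    Without it the mesh is single-region with no membrane edges.
    """
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    if interface_x is not None and not np.any(np.isclose(xs, interface_x)):
        raise GeometryError("interface_x must coincide with a grid line")
    xx, yy = np.meshgrid(xs, ys)
    vertices = np.column_stack([xx.ravel(), yy.ravel()])

    def vid(i, j):  # row j, column i
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    triangles = np.asarray(tris, dtype=np.int64)
    centroids = vertices[triangles].mean(axis=1)
    if interface_x is None:
        region = np.full(len(triangles), CYTOPLASM, dtype=np.int8)
    else:
        region = np.where(centroids[:, 0] < interface_x, NUCLEUS, CYTOPLASM).astype(np.int8)
    return TriMesh(
        vertices=vertices,
        triangles=triangles,
        element_region=region,
        element_bleach=np.zeros(len(triangles), dtype=bool),
    )


def region_measures(mesh: TriMesh) -> dict[str, float]:
    """Areas per region, membrane length and bleach area of a mesh."""
    areas = mesh.areas
    mem = mesh.edge_class == EDGE_MEMBRANE
    return {
        "cytoplasm_area": float(areas[mesh.element_region == CYTOPLASM].sum()),
        "nucleus_area": float(areas[mesh.element_region == NUCLEUS].sum()),
        "cell_area": float(areas.sum()),
        "membrane_length": float(mesh.edge_lengths()[mem].sum()),
        "bleach_area": float(areas[mesh.element_bleach].sum()),
    }
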