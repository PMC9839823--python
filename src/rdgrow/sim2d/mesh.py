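"""Planar triangulations, in-built domain generators and metric bookkeeping.

Meshes are generated without an external mesher: the boundary curve is
resampled at the target size, interior points are laid on a hexagonal
lattice clipped away from the boundary, and a Delaunay triangulation is
filtered to the (possibly non-convex) domain interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

__all__ = [
    "PlanarMesh",
    "MetricField",
    "DomainSpec2D",
    "generate_domain",
    "compute_metric",
    "boundary_curvature_stats",
    "dumbbell_half_width",
    "mesh_polygon",
    "triangle_quality",
]


@dataclass
class PlanarMesh:
    """Lagrangian triangulation with current Eulerian node positions.

    ``X`` are the reference coordinates (the configuration at the last
    remesh), ``x`` the current positions; both (n, 2). ``boundary_loop``
    is an ordered, counter-clockwise index loop of the boundary nodes.
    """

    X: np.ndarray
    triangles: np.ndarray
    x: np.ndarray = None
    boundary_loop: np.ndarray = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.x is None:
            self.x = self.X.copy()
        else:
            self.x = np.asarray(self.x, dtype=float)
        if self.boundary_loop is None:
            self.boundary_loop = _boundary_loop(self.triangles, self.X)
        areas = _signed_areas(self.x, self.triangles)
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise ValueError(f"element {bad} is inverted (signed area {areas[bad]:.3g})")

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def boundary_polyline(self) -> np.ndarray:
        return self.x[self.boundary_loop]

    def area(self) -> float:
        return float(np.sum(_signed_areas(self.x, self.triangles)))

    def element_areas(self) -> np.ndarray:
        return _signed_areas(self.x, self.triangles)

    def copy(self) -> "PlanarMesh":
        return PlanarMesh(
            self.X.copy(), self.triangles.copy(), self.x.copy(), self.boundary_loop.copy()
        )


@dataclass(frozen=True)
class MetricField:
    """Per-element dilation mu and inverse-metric entries (H11, H12, H22)."""

    mu: np.ndarray
    H11: np.ndarray
    H12: np.ndarray
    H22: np.ndarray


@dataclass(frozen=True)
class DomainSpec2D:
    """In-built initial geometries.

    shape: "disk" (radius), "dumbbell" (two lobes joined by a channel of
    half-width 0.01 at the waist), "star" (lobes, amplitude, radius) or
    "polygon" (explicit vertices). ``h`` is the target mesh size.
    """

    shape: str
    h: float = 0.1
    radius: float = 3.0
    lobes: int = 5
    amplitude: float = 0.3
    vertices: Optional[Sequence] = None
    truncation: float = 0.995

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "dumbbell", "star", "polygon"):
            raise ValueError(f"unknown domain shape {self.shape!r}")
        if self.h <= 0:
            raise ValueError("target mesh size must be positive")
        if self.shape == "polygon" and self.vertices is None:
            raise ValueError("polygon domain requires vertices")


# ----------------------------------------------------------------------------
# geometry helpers


def _signed_areas(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = coords[tris]
    return 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


def _boundary_loop(tris: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Ordered CCW loop of boundary nodes (edges used by exactly one triangle)."""
    edges: dict[tuple[int, int], int] = {}
    for tri in tris:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    boundary = [e for e, cnt in edges.items() if cnt == 1]
    if not boundary:
        raise ValueError("mesh has no boundary")
    nbr: dict[int, list[int]] = {}
    for a, b in boundary:
        nbr.setdefault(a, []).append(b)
        nbr.setdefault(b, []).append(a)
    for node, ns in nbr.items():
        if len(ns) != 2:
            raise ValueError(f"boundary is not a simple closed polyline at node {node}")
    start = boundary[0][0]
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [n for n in nbr[cur] if n != prev]
        nxt = nxt[0]
        if nxt == start:
            break
        loop.append(nxt)
        prev, cur = cur, nxt
    if len(loop) != len(nbr):
        raise ValueError("boundary has more than one loop (domain not simply connected)")
    loop = np.asarray(loop, dtype=np.int64)
    ring = coords[loop]
    area = 0.5 * np.sum(
        ring[:, 0] * np.roll(ring[:, 1], -1) - np.roll(ring[:, 0], -1) * ring[:, 1]
    )
    if area < 0:
        loop = loop[::-1].copy()
    return loop


def _resample_polyline(points: np.ndarray, spacing) -> np.ndarray:
    """Resample a closed polyline at (possibly position-dependent) spacing."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if callable(spacing):
        out = []
        pos = 0.0
        while pos < total:
            xy = _point_at(closed, s, pos)
            out.append(xy)
            pos += max(spacing(xy), 1e-6)
        return np.asarray(out)
    n = max(int(np.ceil(total / spacing)), 8)
    targets = np.linspace(0.0, total, n, endpoint=False)
    return np.asarray([_point_at(closed, s, si) for si in targets])


def _point_at(closed: np.ndarray, s: np.ndarray, pos: float) -> np.ndarray:
    i = int(np.searchsorted(s, pos, side="right")) - 1
    i = min(i, len(s) - 2)
    denom = s[i + 1] - s[i]
    w = 0.0 if denom == 0 else (pos - s[i]) / denom
    return (1 - w) * closed[i] + w * closed[i + 1]


def _hex_lattice(bbox: tuple, h: float) -> np.ndarray:
    x0, y0, x1, y1 = bbox
    dy = h * np.sqrt(3.0) / 2.0
    rows = []
    y = y0
    row = 0
    while y <= y1:
        xs = np.arange(x0 + (h / 2.0 if row % 2 else 0.0), x1 + h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    if not rows:
        return np.empty((0, 2))
    return np.vstack(rows)


def mesh_polygon(
    boundary: np.ndarray,
    h: float,
    spacing=None,
    resample_boundary: bool = True,
) -> PlanarMesh:
    """Triangulate the interior of a simple closed polyline.

    Interior points come from a hexagonal lattice kept a safe distance from
    the boundary; a Delaunay triangulation is filtered to triangles whose
    centroid and edge midpoints lie inside the polygon.
    """
    boundary = np.asarray(boundary, dtype=float)
    poly = Polygon(boundary)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("boundary polyline is self-intersecting or degenerate")
    if resample_boundary:
        bpts = _resample_polyline(boundary, spacing if spacing is not None else h)
    else:
        bpts = boundary
    inner = poly.buffer(-0.55 * h)
    lattice = _hex_lattice(poly.bounds, h)
    if lattice.size and not inner.is_empty:
        keep = shapely.contains_xy(inner, lattice[:, 0], lattice[:, 1])
        interior = lattice[keep]
    else:
        interior = np.empty((0, 2))
    pts = np.vstack([bpts, interior])
    tri = Delaunay(pts)
    cells = tri.simplices
    # filter to the domain: centroid and all edge midpoints must be inside
    probe = poly.buffer(1e-9 * max(poly.bounds[2] - poly.bounds[0], 1.0))
    cen = pts[cells].mean(axis=1)
    ok = shapely.contains_xy(probe, cen[:, 0], cen[:, 1])
    for i, j in ((0, 1), (1, 2), (2, 0)):
        mid = 0.5 * (pts[cells[:, i]] + pts[cells[:, j]])
        ok &= shapely.contains_xy(probe, mid[:, 0], mid[:, 1])
    cells = cells[ok]
    if cells.size == 0:
        raise ValueError("triangulation empty after filtering; h too large?")
    # drop degenerate slivers on the boundary
    areas = np.abs(_signed_areas(pts, cells))
    cells = cells[areas > 1e-12 * np.median(areas)]
    # renumber used nodes
    used = np.unique(cells)
    remap = -np.ones(pts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    coords = pts[used]
    cells = remap[cells]
    # orient positively
    neg = _signed_areas(coords, cells) < 0
    cells[neg] = cells[neg][:, ::-1]
    return PlanarMesh(coords, cells)


def _local_edge_scale(ring: np.ndarray, window: int = 11) -> np.ndarray:
    """Rolling-median edge length around a closed ring (one value per edge)."""
    from scipy.ndimage import median_filter

    e = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
    return median_filter(e, size=min(window, len(e)), mode="wrap")


def ring_bunching(ring: np.ndarray) -> float:
    """Smallest edge length relative to its local scale (1 = uniform)."""
    e = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
    return float(np.min(e / np.maximum(_local_edge_scale(ring), 1e-300)))


def heal_ring(ring: np.ndarray, merge_frac: float = 0.5, passes: int = 5) -> np.ndarray:
    """Repair a boundary polyline before re-triangulation.

    Microscopic self-intersection loops (boundary folds from normal motion
    in concave regions) are removed via polygon validity repair, and
    vertices bunched far below the local edge scale are merged. Judging
    bunching against the local scale keeps deliberately fine sampling
    (e.g. a thin channel) intact.
    """
    poly = Polygon(ring)
    if not poly.is_valid:
        from shapely.validation import make_valid

        fixed = make_valid(poly)
        if fixed.geom_type == "GeometryCollection" or fixed.geom_type == "MultiPolygon":
            parts = [g for g in getattr(fixed, "geoms", [fixed]) if g.geom_type == "Polygon"]
            if not parts:
                raise ValueError("boundary polyline could not be repaired")
            fixed = max(parts, key=lambda g: g.area)
        ring = np.asarray(fixed.exterior.coords)[:-1]
    for _ in range(passes):
        n = len(ring)
        if n < 8:
            break
        e = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
        scale = _local_edge_scale(ring)
        short = e < merge_frac * scale
        # vertex i sits between edges i-1 and i; drop when both are short
        drop = short & np.roll(short, 1)
        if not np.any(drop):
            break
        keep = np.ones(n, dtype=bool)
        skip_next = False
        for i in range(n):
            if skip_next:
                skip_next = False
                continue
            if drop[i]:
                keep[i] = False
                skip_next = True  # never drop adjacent vertices in one pass
        ring = ring[keep]
    return ring


def dumbbell_half_width(x: np.ndarray) -> np.ndarray:
    """Half-width w(x) = (x^8 + 0.01) sqrt(1 - x^8) of the dumbbell profile."""
    x8 = np.clip(np.asarray(x, dtype=float) ** 8, 0.0, 1.0)
    return (x8 + 0.01) * np.sqrt(1.0 - x8)


def _dumbbell_boundary(h: float, truncation: float) -> np.ndarray:
    """Closed CCW polyline |y| <= w(x), |x| <= truncation, adaptively sampled."""
    xs = [-truncation]
    while xs[-1] < truncation:
        x = xs[-1]
        w = float(dumbbell_half_width(x))
        step = float(np.clip(1.2 * w, 0.2 * h, h))
        xs.append(min(x + step, truncation))
    xs = np.asarray(xs)
    top = np.column_stack([xs, dumbbell_half_width(xs)])
    bot = np.column_stack([xs[::-1], -dumbbell_half_width(xs[::-1])])
    ring = np.vstack([top, bot])  # the half-widths never vanish, so no duplicates
    return ring[::-1]  # CCW


def generate_domain(spec: DomainSpec2D) -> PlanarMesh:
    """Conforming triangulation of an in-built domain; x == X, mu == 1."""
    if spec.shape == "disk":
        n = max(int(np.ceil(2 * np.pi * spec.radius / spec.h)), 12)
        th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        ring = spec.radius * np.column_stack([np.cos(th), np.sin(th)])
        return mesh_polygon(ring, spec.h, resample_boundary=False)
    if spec.shape == "star":
        r_of = lambda th: spec.radius * (1.0 + spec.amplitude * np.cos(spec.lobes * th))
        th = np.linspace(0.0, 2 * np.pi, 2048, endpoint=False)
        ring = (r_of(th)[:, None]) * np.column_stack([np.cos(th), np.sin(th)])
        return mesh_polygon(ring, spec.h)
    if spec.shape == "dumbbell":
        ring = _dumbbell_boundary(spec.h, spec.truncation)
        return mesh_polygon(ring, spec.h, resample_boundary=False)
    # polygon
    verts = np.asarray(spec.vertices, dtype=float)
    return mesh_polygon(verts, spec.h)


# ----------------------------------------------------------------------------
# metric


def compute_metric(mesh: PlanarMesh) -> MetricField:
    """Per-element dx/dX from the affine reference->current map; mu = |det|."""
    Xp = mesh.X[mesh.triangles]
    xp = mesh.x[mesh.triangles]
    EX = np.stack([Xp[:, 1] - Xp[:, 0], Xp[:, 2] - Xp[:, 0]], axis=-1)  # (nt,2,2)
    Ex = np.stack([xp[:, 1] - xp[:, 0], xp[:, 2] - xp[:, 0]], axis=-1)
    detX = EX[:, 0, 0] * EX[:, 1, 1] - EX[:, 0, 1] * EX[:, 1, 0]
    invEX = np.empty_like(EX)
    invEX[:, 0, 0] = EX[:, 1, 1]
    invEX[:, 0, 1] = -EX[:, 0, 1]
    invEX[:, 1, 0] = -EX[:, 1, 0]
    invEX[:, 1, 1] = EX[:, 0, 0]
    invEX /= detX[:, None, None]
    F = Ex @ invEX  # dx/dX, columns dx/dX1, dx/dX2
    dX1 = F[:, :, 0]
    dX2 = F[:, :, 1]
    det = dX1[:, 0] * dX2[:, 1] - dX1[:, 1] * dX2[:, 0]
    if np.any(det <= 0):
        bad = int(np.argmin(det))
        raise ValueError(f"element {bad} inverted under the current map (mu <= 0)")
    n1 = np.einsum("ij,ij->i", dX1, dX1)
    n2 = np.einsum("ij,ij->i", dX2, dX2)
    cross = np.einsum("ij,ij->i", dX1, dX2)
    mu = np.sqrt(n1 * n2 - cross**2)
    return MetricField(
        mu=mu, H11=n2 / mu**2, H12=-cross / mu**2, H22=n1 / mu**2
    )


def triangle_quality(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Per-element 2 * inradius / circumradius (equilateral -> 1)."""
    p = coords[tris]
    a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    b = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    s = 0.5 * (a + b + c)
    area = np.abs(_signed_areas(coords, tris))
    r_in = area / s
    r_circ = a * b * c / (4.0 * np.maximum(area, 1e-300))
    return 2.0 * r_in / r_circ


def boundary_curvature_stats(mesh: PlanarMesh) -> dict:
    """Discrete boundary curvature (turning angle over arc length), perimeter,
    area and the isoperimetric ratio P^2 / (4 pi A)."""
    ring = mesh.boundary_polyline
    if ring.shape[0] < 4:
        raise ValueError("need at least 4 boundary vertices")
    nxt = np.roll(ring, -1, axis=0)
    prv = np.roll(ring, 1, axis=0)
    e_in = ring - prv
    e_out = nxt - ring
    ang_in = np.arctan2(e_in[:, 1], e_in[:, 0])
    ang_out = np.arctan2(e_out[:, 1], e_out[:, 0])
    turn = np.angle(np.exp(1j * (ang_out - ang_in)))
    ds = 0.5 * (np.linalg.norm(e_in, axis=1) + np.linalg.norm(e_out, axis=1))
    kappa = turn / ds
    perim = float(np.sum(np.linalg.norm(e_out, axis=1)))
    area = float(
        0.5 * np.sum(ring[:, 0] * nxt[:, 1] - nxt[:, 0] * ring[:, 1])
    )
    return {
        "mean_curvature": float(np.mean(kappa)),
        "sd_curvature": float(np.std(kappa)),
        "perimeter": perim,
        "area": area,
        "isoperimetric_ratio": perim**2 / (4.0 * np.pi * area),
    }
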