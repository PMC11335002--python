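"""Low-level geometry kernel.

Deterministic, pure-numpy routines shared by the mesh layer and the bending
engine:

* exact point-in-mesh parity tests (ray casting along +X, vectorised),
* occupancy grids built from per-column parity intervals (the "voxel"
  overlap backend),
* planar boundary-loop triangulation (ear clipping) used to re-cap cut
  meshes,
* rigid transforms about arbitrary centres.

All solids are closed triangle meshes; a "part" is one closed component.
Queries against a multi-part solid treat it as the union of its parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial.transform import Rotation

# Parity tests use strictly positive margins so that shared triangle edges
# are not double counted on generic inputs; grids are given a tiny
# deterministic offset to avoid querying exactly on faces of axis-aligned
# geometry.
_EPS = 1e-12
# fraction of a pitch by which ray columns are offset along y (irrational-ish
# so axis-aligned geometry cannot land a column exactly on a projected edge)
_Y_JITTER = 7.346e-4


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if not np.isfinite(norm) or norm == 0.0:
        raise ValueError("rotation axis must be a non-zero finite vector")
    return Rotation.from_rotvec(axis / norm * np.radians(angle_deg)).as_matrix()


def rotate_points(
    points: np.ndarray, axis: np.ndarray, angle_deg: float, center: np.ndarray
) -> np.ndarray:
    """Rotate ``points`` about the line through ``center`` along ``axis``."""
    center = np.asarray(center, dtype=float)
    R = rotation_matrix(axis, angle_deg)
    return (np.asarray(points, dtype=float) - center) @ R.T + center


def points_in_triangles_parity(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact point-in-solid test by ray parity.

    Casts a ray along +X from every point and counts crossings with the
    closed surface given as ``triangles`` (n, 3, 3). Points exactly on the
    surface are classified arbitrarily (measure-zero set).
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return np.zeros(0, dtype=bool)
    tri = np.asarray(triangles, dtype=float)
    # plane: n . x = d ; skip triangles parallel to the ray (n_x == 0)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    keep = np.abs(n[:, 0]) > _EPS * np.maximum(1.0, np.abs(n).max())
    tri = tri[keep]
    n = n[keep]
    if len(tri) == 0:
        return np.zeros(len(points), dtype=bool)
    d = np.einsum("ij,ij->i", n, tri[:, 0])

    a = tri[:, 0, 1:]  # (F, 2) projections on (y, z)
    b = tri[:, 1, 1:]
    c = tri[:, 2, 1:]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (
        b[:, 1] - a[:, 1]
    )
    ok = np.abs(det) > _EPS
    a, b, c, n, d, det, tri0 = a[ok], b[ok], c[ok], n[ok], d[ok], det[ok], tri[ok, 0]
    if len(det) == 0:
        return np.zeros(len(points), dtype=bool)

    inside = np.zeros(len(points), dtype=bool)
    chunk = max(1, int(4e6 // max(len(det), 1)))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        py = p[:, 1][:, None] - a[None, :, 0]
        pz = p[:, 2][:, None] - a[None, :, 1]
        u = ((c[:, 1] - a[:, 1]) * py - (c[:, 0] - a[:, 0]) * pz) / det
        v = (-(b[:, 1] - a[:, 1]) * py + (b[:, 0] - a[:, 0]) * pz) / det
        hit2d = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        # x of the plane at the projected point
        x_hit = (
            d[None, :]
            - n[None, :, 1] * p[:, 1][:, None]
            - n[None, :, 2] * p[:, 2][:, None]
        ) / n[None, :, 0]
        crossings = (hit2d & (x_hit > p[:, 0][:, None])).sum(axis=1)
        inside[lo : lo + chunk] = (crossings % 2) == 1
    return inside


def points_in_parts(points: np.ndarray, parts: list[np.ndarray]) -> np.ndarray:
    """Point-in-union test for a list of closed triangle arrays."""
    points = np.asarray(points, dtype=float)
    inside = np.zeros(len(points), dtype=bool)
    for tri in parts:
        todo = ~inside
        if not todo.any():
            break
        lo = tri.reshape(-1, 3).min(axis=0)
        hi = tri.reshape(-1, 3).max(axis=0)
        cand = todo & np.all((points >= lo - _EPS) & (points <= hi + _EPS), axis=1)
        if cand.any():
            inside[cand] |= points_in_triangles_parity(points[cand], tri)
    return inside


def _column_fill(tri: np.ndarray, origin: np.ndarray, pitch: float, shape) -> np.ndarray:
    """Parity-fill one closed part onto a cell-centre grid.

    Grid cell (i, j, k) has centre ``origin + (i+.5, j+.5, k+.5) * pitch``.
    For every (y, z) column of centres the exact surface crossings along x
    are computed; cells whose centre lies inside an odd interval are set.
    """
    nx, ny, nz = shape
    occ = np.zeros(shape, dtype=bool)
    # columns are nudged off exact cell centres along y so that rays do not
    # graze shared triangle edges (e.g. the diagonals of quad faces); z is
    # left exact to preserve bilateral (left/right) mirror symmetry
    ycent = origin[1] + (np.arange(ny) + 0.5 + _Y_JITTER) * pitch
    zcent = origin[2] + (np.arange(nz) + 0.5) * pitch
    xcent0 = origin[0] + 0.5 * pitch

    # collect crossings per column
    col_cross: dict[tuple[int, int], list[float]] = {}
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    scale = np.abs(n).max() if len(n) else 1.0
    for f in range(len(tri)):
        if abs(n[f, 0]) <= _EPS * max(1.0, scale):
            continue
        a, b, c = tri[f, :, 1:]
        ymin, ymax = min(a[0], b[0], c[0]), max(a[0], b[0], c[0])
        zmin, zmax = min(a[1], b[1], c[1]), max(a[1], b[1], c[1])
        j0 = max(0, int(np.ceil((ymin - origin[1]) / pitch - 0.5)))
        j1 = min(ny - 1, int(np.floor((ymax - origin[1]) / pitch - 0.5)))
        k0 = max(0, int(np.ceil((zmin - origin[2]) / pitch - 0.5)))
        k1 = min(nz - 1, int(np.floor((zmax - origin[2]) / pitch - 0.5)))
        if j1 < j0 or k1 < k0:
            continue
        yy, zz = np.meshgrid(ycent[j0 : j1 + 1], zcent[k0 : k1 + 1], indexing="ij")
        det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        if abs(det) < _EPS:
            continue
        py = yy - a[0]
        pz = zz - a[1]
        u = ((c[1] - a[1]) * py - (c[0] - a[0]) * pz) / det
        v = (-(b[1] - a[1]) * py + (b[0] - a[0]) * pz) / det
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not hit.any():
            continue
        dplane = float(n[f] @ tri[f, 0])
        xs = (dplane - n[f, 1] * yy - n[f, 2] * zz) / n[f, 0]
        js, ks = np.nonzero(hit)
        for jj, kk, xv in zip(js + j0, ks + k0, xs[hit]):
            col_cross.setdefault((jj, kk), []).append(float(xv))

    for (j, k), xs in col_cross.items():
        xs = sorted(xs)
        # collapse numerically duplicated crossings (ray through an edge)
        merged: list[float] = []
        for x in xs:
            if merged and abs(x - merged[-1]) < 1e-9:
                merged.pop()
            else:
                merged.append(x)
        if len(merged) % 2 == 1:
            # degenerate column (ray grazing a vertex): drop it
            continue
        for lo_x, hi_x in zip(merged[0::2], merged[1::2]):
            i0 = max(0, int(np.ceil((lo_x - xcent0) / pitch)))
            i1 = min(nx - 1, int(np.floor((hi_x - xcent0) / pitch)))
            if i1 >= i0:
                occ[i0 : i1 + 1, j, k] = True
    return occ


@dataclass
class OccupancyGrid:
    """Cell-centre occupancy of a (multi-part) solid on a regular grid."""

    origin: np.ndarray
    pitch: float
    occupied: np.ndarray  # (nx, ny, nz) bool
    core: np.ndarray = field(init=False)
    shell: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # "core" cells are surrounded by occupied cells; points falling in
        # them are accepted without the exact narrow-phase test. The "shell"
        # (everything within one cell of the surface, inside or out) gets
        # the exact parity test so thin contact slivers are never missed.
        self.core = binary_erosion(self.occupied)
        self.shell = binary_dilation(self.occupied) & ~self.core

    @classmethod
    def from_parts(cls, parts: list[np.ndarray], pitch: float) -> "OccupancyGrid":
        pts = np.vstack([t.reshape(-1, 3) for t in parts])
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        # snap the grid to the absolute lattice of the pitch: solids that
        # differ only far from a contact zone then share cell centres in the
        # shared region, and the lattice is mirror-symmetric about z = 0
        origin = np.floor(lo / pitch - 1e-9) * pitch
        shape = np.maximum(1, np.ceil((hi - origin) / pitch + 1e-9).astype(int))
        occ = np.zeros(tuple(shape), dtype=bool)
        for tri in parts:
            occ |= _column_fill(tri, origin, pitch, tuple(shape))
        return cls(origin=origin, pitch=pitch, occupied=occ)

    @property
    def cell_volume(self) -> float:
        return float(self.pitch**3)

    @property
    def volume(self) -> float:
        return float(self.occupied.sum()) * self.cell_volume

    def cell_centers(self, core_only: bool = False) -> np.ndarray:
        """Sample points of occupied cells (exact interior points of the
        solid: the jittered column coordinates the parity fill used)."""
        idx = np.argwhere(self.core if core_only else self.occupied)
        pts = self.origin + (idx + 0.5) * self.pitch
        pts[:, 1] += _Y_JITTER * self.pitch
        return pts

    def _indices(self, points: np.ndarray):
        rel = (np.asarray(points, dtype=float) - self.origin) / self.pitch
        idx = np.floor(rel).astype(int)
        shape = np.array(self.occupied.shape)
        valid = np.all((idx >= 0) & (idx < shape), axis=1)
        return idx, valid

    def lookup(self, points: np.ndarray, which: str = "occupied") -> np.ndarray:
        """Boolean occupancy at each point (False outside the grid)."""
        data = self.occupied if which == "occupied" else self.core
        idx, valid = self._indices(points)
        out = np.zeros(len(points), dtype=bool)
        if valid.any():
            iv = idx[valid]
            out[valid] = data[iv[:, 0], iv[:, 1], iv[:, 2]]
        return out

    def classify(self, points: np.ndarray):
        """Split points into (certain inside, boundary candidates).

        Points in core cells are inside; points in the surface shell need
        the exact test; the rest are outside.
        """
        idx, valid = self._indices(points)
        inside = np.zeros(len(points), dtype=bool)
        boundary = np.zeros(len(points), dtype=bool)
        if valid.any():
            iv = idx[valid]
            cor = self.core[iv[:, 0], iv[:, 1], iv[:, 2]]
            shl = self.shell[iv[:, 0], iv[:, 1], iv[:, 2]]
            w = np.nonzero(valid)[0]
            inside[w[cor]] = True
            boundary[w[shl]] = True
        return inside, boundary


def contained_volume(
    points: np.ndarray,
    cell_volume: float,
    grid: OccupancyGrid,
    exact_parts: list[np.ndarray],
) -> float:
    """Volume of ``points`` (interior samples, each worth ``cell_volume``)
    that fall inside the solid described by ``grid`` + ``exact_parts``."""
    inside, boundary = grid.classify(points)
    n_inside = int(inside.sum())
    if boundary.any():
        n_inside += int(points_in_parts(points[boundary], exact_parts).sum())
    return n_inside * cell_volume


# ---------------------------------------------------------------------------
# boundary loops and ear-clip capping


def boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered vertex loops of edges referenced by exactly one face."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bound = edges[counts[inv] == 1]
    nxt = {int(a): int(b) for a, b in bound}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur, None)
            if cur is None:  # open chain; abandon
                loop = None
                break
        if loop is None:
            nxt.pop(start, None)
            continue
        nxt.pop(start, None)
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def triangulate_loop(points2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple planar polygon."""
    n = len(points2d)
    if n < 3:
        return []
    idx = list(range(n))
    # ensure CCW
    area2 = 0.0
    for i in range(n):
        x1, y1 = points2d[i]
        x2, y2 = points2d[(i + 1) % n]
        area2 += x1 * y2 - x2 * y1
    if area2 < 0:
        idx = idx[::-1]

    def cross(o, a, b):
        return (points2d[a][0] - points2d[o][0]) * (points2d[b][1] - points2d[o][1]) - (
            points2d[a][1] - points2d[o][1]
        ) * (points2d[b][0] - points2d[o][0])

    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        clipped = False
        for i in range(m):
            o, a, b = idx[(i - 1) % m], idx[i], idx[(i + 1) % m]
            if cross(o, a, b) <= 1e-14:
                continue
            # no other vertex inside candidate ear
            ear_ok = True
            for j in idx:
                if j in (o, a, b):
                    continue
                if (
                    cross(o, a, j) >= -1e-14
                    and cross(a, b, j) >= -1e-14
                    and cross(b, o, j) >= -1e-14
                ):
                    ear_ok = False
                    break
            if ear_ok:
                tris.append((o, a, b))
                idx.pop(i)
                clipped = True
                break
        if not clipped:  # numerically stuck: fan the remainder
            break
    if len(idx) >= 3:
        for i in range(1, len(idx) - 1):
            tris.append((idx[0], idx[i], idx[i + 1]))
    return tris
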