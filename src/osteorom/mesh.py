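"""Geometry substrate: mesh I/O, rigid transforms, overlap measurement,
merging and planar cutting.

A :class:`TriMesh` is a closed triangulated solid in millimetres. It may be
composed of several closed *parts* (e.g. a vertebra built from a centrum
plus neural-arch and facet elements, or a vertebra merged with an
intercentrum). Parts are treated as a union: containment, overlap and
volume all refer to the union of the parts. Keeping parts separate makes
point-in-solid parity tests exact even when parts interpenetrate.

Overlap between two solids is measured with a deterministic grid backend:
interior sample points of one solid (exact parity at the cell centres of a
regular grid) are tested against the other solid, with an exact
narrow-phase test in boundary cells, and the result is symmetrised. Contact
onset is additionally detected exactly from mesh vertices, so a zero
intersection threshold behaves like true first contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh as _tm

from . import _kernel


class MeshError(ValueError):
    """Invalid or degenerate mesh input."""


class GeometryError(RuntimeError):
    """A geometric computation failed (e.g. overlap on unusable meshes)."""


@dataclass
class TriMesh:
    """Closed triangulated solid, possibly a union of closed parts."""

    parts: list[_tm.Trimesh]
    label: str = ""
    source: str = ""
    _grid_cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -------------------------------------------------

    @classmethod
    def from_arrays(cls, vertices, faces, label: str = "", source: str = "") -> "TriMesh":
        m = _tm.Trimesh(
            vertices=np.asarray(vertices, float),
            faces=np.asarray(faces, int),
            process=False,
        )
        return cls(parts=[m], label=label, source=source)

    @classmethod
    def from_trimesh(cls, mesh: _tm.Trimesh, label: str = "", source: str = "") -> "TriMesh":
        return cls(parts=[mesh], label=label, source=source)

    def copy(self) -> "TriMesh":
        return TriMesh(
            parts=[p.copy() for p in self.parts], label=self.label, source=self.source
        )

    # -- basic properties ----------------------------------------------

    @classmethod
    def empty(cls, label: str = "") -> "TriMesh":
        return cls(parts=[], label=label)

    @property
    def vertices(self) -> np.ndarray:
        if not self.parts:
            return np.zeros((0, 3))
        return np.vstack([p.vertices for p in self.parts])

    @property
    def faces(self) -> np.ndarray:
        out = []
        off = 0
        for p in self.parts:
            out.append(np.asarray(p.faces) + off)
            off += len(p.vertices)
        return np.vstack(out)

    @property
    def triangles(self) -> list[np.ndarray]:
        return [np.asarray(p.triangles) for p in self.parts]

    @property
    def is_watertight(self) -> bool:
        return all(p.is_watertight for p in self.parts)

    @property
    def bounds(self) -> np.ndarray:
        v = self.vertices
        return np.array([v.min(axis=0), v.max(axis=0)])

    @property
    def area(self) -> float:
        return float(sum(p.area for p in self.parts))

    def _bboxes_disjoint(self) -> bool:
        for i in range(len(self.parts)):
            for j in range(i + 1, len(self.parts)):
                bi = self.parts[i].bounds
                bj = self.parts[j].bounds
                if np.all(bi[0] <= bj[1]) and np.all(bj[0] <= bi[1]):
                    return False
        return True

    @property
    def volume(self) -> float:
        """Enclosed volume of the union of parts.

        Exact (divergence theorem) when parts cannot overlap; otherwise a
        grid estimate of the union volume at the default pitch.
        """
        return self.union_volume()

    def union_volume(self, pitch: float | None = None) -> float:
        if not self.parts:
            return 0.0
        if len(self.parts) == 1 or self._bboxes_disjoint():
            return float(sum(abs(p.volume) for p in self.parts))
        grid = self.occupancy(pitch if pitch is not None else self.default_pitch())
        return grid.volume

    def mean_edge_length(self) -> float:
        tot, n = 0.0, 0
        for p in self.parts:
            e = p.vertices[p.edges_unique]
            tot += np.linalg.norm(e[:, 0] - e[:, 1], axis=1).sum()
            n += len(e)
        return tot / max(n, 1)

    def default_pitch(self) -> float:
        """Default grid pitch: mean edge length / 4, clamped so grids stay
        tractable on very coarse meshes."""
        pitch = self.mean_edge_length() / 4.0
        ext = self.bounds[1] - self.bounds[0]
        pitch = min(pitch, float(ext.max()) / 16.0)
        return max(pitch, float(ext.max()) / 1024.0)

    def occupancy(self, pitch: float) -> _kernel.OccupancyGrid:
        key = round(float(pitch), 12)
        if key not in self._grid_cache:
            self._grid_cache[key] = _kernel.OccupancyGrid.from_parts(
                self.triangles, pitch
            )
        return self._grid_cache[key]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact point-in-union parity test."""
        return _kernel.points_in_parts(points, self.triangles)


# ---------------------------------------------------------------------------
# I/O


def load_mesh(path, file_format: str | None = None, label: str = "") -> TriMesh:
    """Load an OBJ/PLY/STL surface, repair it and split closed parts.

    The repair pass welds duplicate vertices and drops degenerate faces;
    the result is split into connected components so that unioned,
    interpenetrating sub-solids stored in one file remain individually
    closed for parity queries. Non-watertight results are flagged with a
    warning but still usable (the grid backend is tolerant of small
    defects).
    """
    try:
        raw = _tm.load(str(path), file_type=file_format, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001
        raise MeshError(f"could not read mesh file {path!r}: {exc}") from exc
    if not isinstance(raw, _tm.Trimesh) or len(raw.faces) == 0:
        raise MeshError(f"file {path!r} contains no triangle faces")
    raw = _tm.Trimesh(vertices=raw.vertices, faces=raw.faces, process=True)
    raw.update_faces(raw.nondegenerate_faces())
    raw.remove_unreferenced_vertices()
    if len(raw.faces) == 0:
        raise MeshError(f"mesh in {path!r} is degenerate (no valid faces)")
    if not np.isfinite(raw.vertices).all():
        raise MeshError(f"mesh in {path!r} has non-finite coordinates")
    parts = raw.split(only_watertight=False)
    parts = [p for p in parts if len(p.faces) > 0]
    if not parts:
        raise MeshError(f"mesh in {path!r} is degenerate (no valid faces)")
    out = TriMesh(parts=list(parts), label=label or str(path), source=str(path))
    if not out.is_watertight:
        warnings.warn(
            f"mesh {path!r} is not watertight; grid overlap backend engaged",
            stacklevel=2,
        )
    return out


def save_mesh(mesh: TriMesh, path) -> None:
    """Write all parts of a mesh concatenated to one OBJ/PLY/STL file."""
    combined = _tm.util.concatenate(mesh.parts) if len(mesh.parts) > 1 else mesh.parts[0]
    combined.export(str(path))


# ---------------------------------------------------------------------------
# rigid transforms


def rigid_rotate(mesh: TriMesh, axis, angle_deg: float, center) -> TriMesh:
    """Rotate a mesh rigidly about the line through ``center`` along ``axis``."""
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    out = mesh.copy()
    for p in out.parts:
        p.vertices = _kernel.rotate_points(p.vertices, axis, angle_deg, center)
    return out


def rigid_translate(mesh: TriMesh, offset) -> TriMesh:
    out = mesh.copy()
    off = np.asarray(offset, float)
    for p in out.parts:
        p.vertices = p.vertices + off
    # occupancy grids translate rigidly with the solid
    out._grid_cache = {
        k: _kernel.OccupancyGrid(origin=g.origin + off, pitch=g.pitch, occupied=g.occupied)
        for k, g in mesh._grid_cache.items()
    }
    return out


# ---------------------------------------------------------------------------
# overlap


def intersection_volume(
    mesh_a: TriMesh, mesh_b: TriMesh, pitch: float | None = None
) -> float:
    """Symmetrised grid estimate of the volume shared by two solids."""
    ba, bb = mesh_a.bounds, mesh_b.bounds
    if np.any(ba[1] < bb[0]) or np.any(bb[1] < ba[0]):
        return 0.0
    if pitch is None:
        pitch = min(mesh_a.default_pitch(), mesh_b.default_pitch())
    ga = mesh_a.occupancy(pitch)
    gb = mesh_b.occupancy(pitch)
    tri_a, tri_b = mesh_a.triangles, mesh_b.triangles
    v_b_in_a = _kernel.contained_volume(gb.cell_centers(), gb.cell_volume, ga, tri_a)
    v_a_in_b = _kernel.contained_volume(ga.cell_centers(), ga.cell_volume, gb, tri_b)
    return 0.5 * (v_b_in_a + v_a_in_b)


def overlap_fraction(
    mesh_a: TriMesh,
    mesh_b: TriMesh,
    normalization: str = "mean_volume",
    pitch: float | None = None,
) -> float:
    """Overlap of two solids as a fraction of their mean measure.

    ``intersection volume / mean(measure(A), measure(B))`` where the
    measure is the grid-estimated volume (default) or the total surface
    area (``normalization='mean_area'``; the result then has units of mm).
    Symmetric in its arguments and 0 for disjoint solids.
    """
    if pitch is None:
        pitch = min(mesh_a.default_pitch(), mesh_b.default_pitch())
    inter = intersection_volume(mesh_a, mesh_b, pitch=pitch)
    if normalization == "mean_volume":
        denom = 0.5 * (mesh_a.occupancy(pitch).volume + mesh_b.occupancy(pitch).volume)
    elif normalization == "mean_area":
        denom = 0.5 * (mesh_a.area + mesh_b.area)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom <= 0:
        raise GeometryError(
            f"cannot normalise overlap of {mesh_a.label!r} and {mesh_b.label!r}: "
            "zero mean measure"
        )
    return inter / denom


def first_contact(mesh_a: TriMesh, mesh_b: TriMesh) -> bool:
    """Exact vertex-in-solid contact test (either direction).

    Detects penetration slivers far thinner than any grid pitch, provided
    the penetrating feature carries a mesh vertex (true for convex
    primitive fixtures at first contact).
    """
    ba, bb = mesh_a.bounds, mesh_b.bounds
    if np.any(ba[1] < bb[0]) or np.any(bb[1] < ba[0]):
        return False
    va = mesh_a.vertices
    cand = va[np.all((va >= bb[0]) & (va <= bb[1]), axis=1)]
    if len(cand) and mesh_b.contains(cand).any():
        return True
    vb = mesh_b.vertices
    cand = vb[np.all((vb >= ba[0]) & (vb <= ba[1]), axis=1)]
    return bool(len(cand) and mesh_a.contains(cand).any())


# ---------------------------------------------------------------------------
# merge and cut


def merge_meshes(mesh_a: TriMesh, mesh_b: TriMesh, label: str = "") -> TriMesh:
    """Union of two solids, kept as a multi-part mesh.

    The result behaves as the union for containment, overlap and volume
    queries; no boolean surgery of the surfaces is performed.
    """
    parts = [p.copy() for p in mesh_a.parts] + [p.copy() for p in mesh_b.parts]
    if not parts:
        raise MeshError("cannot merge two empty meshes")
    return TriMesh(
        parts=parts,
        label=label or f"{mesh_a.label}+{mesh_b.label}",
        source=mesh_a.source,
    )


class EmptyCutError(GeometryError):
    """Cutting removed the whole mesh."""


def cut_above_plane(mesh: TriMesh, plane_point, plane_normal) -> TriMesh:
    """Remove everything on the positive-normal side of a plane.

    Each closed part is sliced and re-capped with an ear-clipped planar
    polygon so the result stays watertight. Parts entirely above the plane
    are dropped; cutting away the whole solid raises :class:`EmptyCutError`.
    """
    n = np.asarray(plane_normal, float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("plane normal must be non-zero")
    n = n / nn
    p0 = np.asarray(plane_point, float)

    kept: list[_tm.Trimesh] = []
    for part in mesh.parts:
        signed = (part.vertices - p0) @ n
        if np.all(signed <= 1e-12):
            kept.append(part.copy())
            continue
        if np.all(signed >= -1e-12):
            continue
        open_mesh = _tm.intersections.slice_mesh_plane(
            part, plane_normal=-n, plane_origin=p0, cap=False
        )
        if open_mesh is None or len(open_mesh.faces) == 0:
            continue
        kept.append(_cap_with_plane(open_mesh, p0, n))
    if not kept:
        raise EmptyCutError("cut plane removed the entire mesh")
    return TriMesh(parts=kept, label=mesh.label, source=mesh.source)


def _cap_with_plane(open_mesh: _tm.Trimesh, p0: np.ndarray, n: np.ndarray) -> _tm.Trimesh:
    """Close the boundary loops of a plane-sliced mesh with flat caps."""
    open_mesh = open_mesh.copy()
    open_mesh.merge_vertices()
    faces = np.asarray(open_mesh.faces)
    verts = np.asarray(open_mesh.vertices)
    loops = _kernel.boundary_loops(faces)
    if not loops:
        return open_mesh
    # in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    new_faces = list(faces)
    for loop in loops:
        pts2d = np.column_stack([verts[loop] @ u, verts[loop] @ v])
        for i, j, k in _kernel.triangulate_loop(pts2d):
            a, b, c = loop[i], loop[j], loop[k]
            tri_n = np.cross(verts[b] - verts[a], verts[c] - verts[a])
            # cap must face the +normal side (outward, solid lies below)
            if tri_n @ n < 0:
                a, b, c = a, c, b
            new_faces.append([a, b, c])
    out = _tm.Trimesh(vertices=verts, faces=np.asarray(new_faces), process=False)
    out.merge_vertices()
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()
    return out
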