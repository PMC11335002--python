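"""Parametric synthetic vertebrae and columns.

Every pipeline stage is testable without CT scans: vertebrae are built from
closed convex primitives (a revolved amphicoelous/procoelous centrum, box
neural arch and spine, tilted zygapophyseal facet plates, optional
crescent-like ventral intercentra) so that all landmark positions and
contact angles have closed forms usable as oracles.

The craniocaudal facet-angle profile is the main functional knob: facets
near 0 degrees from horizontal permit axial rotation (the "open",
pre-diaphragmatic articulation), facets near 90 degrees (parasagittal)
permit sagittal sliding but block axial twist. Endplate ellipticity
(``endplate_aspect`` = mediolateral half-width / dorsoventral half-height)
shifts the disc-limited balance between lateral and sagittal bending:
wide-flat centra favour sagittal bending, tall-narrow centra favour
lateroflexion.

Geometry is in millimetres; vertebra k's local frame has the cranial
endplate rim at x = 0, the centrum axis along +X, +Y dorsal, +Z left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh as _tm

from . import io as _io, mesh as _mesh
from .column import ColumnModel, LandmarkSet, Vertebra, assemble_column


def sigmoid_profile(n: int, lo: float, hi: float, midpoint: float, rate: float = 1.5):
    """Sigmoid craniocaudal gradient: value ``lo`` anteriorly, ``hi``
    posteriorly, switching around vertebra ordinal ``midpoint`` (1-based)."""
    k = np.arange(1, n + 1)
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (k - midpoint)))


@dataclass
class CrescentSpec:
    """Ventral intercentrum dimensions (mm).

    The element is wedge-shaped: its caudal face is tilted ventrally by
    ``wedge_angle`` so that a ventroflexing posterior centrum meets the
    whole face nearly at once (a sharp bony stop), while lateral bending
    only produces thin edge slivers.
    """

    height: float = 5.0  # dorsoventral extent (upward from the ventral rim)
    width: float = 9.0  # mediolateral extent
    lip: float = 1.0  # overlap into the anterior centrum (for merging)
    clearance: float = 0.25  # gap to the posterior cranial face at neutral
    wedge_angle: float = 0.0  # degrees, optional ventral recession of the caudal face


@dataclass
class SyntheticColumnSpec:
    """Parametric description of a generated column.

    Scalar morphological fields may instead be given per vertebra as a
    sequence of length ``n_vertebrae`` (facet angles, spine heights, gaps).
    """

    n_vertebrae: int = 8
    # centrum
    centrum_radius: float = 6.0
    centrum_length: float = 14.0
    concavity_depth: float = 0.6  # endplate dimple depth (10% of radius)
    endplate_aspect: float = 1.0  # half-width (z) / half-height (y)
    centrum_type: str = "amphicoelous"  # or procoelous
    # neural arch + spine
    # the arch roof must clear the zygapophyseal plates so that truncating a
    # neural spine "just above the arch" never touches the facets
    arch_height: float = 7.0
    arch_width: float = 3.0
    spine_height: float | tuple | list = 5.0
    spine_thickness: float = 2.0
    # zygapophyses
    facet_angle: float | tuple | list = 45.0  # degrees from horizontal
    facet_length: float = 8.0
    facet_width: float = 5.0
    facet_thickness: float = 2.5
    facet_clearance: float = 1.1  # articular gap between facet surfaces
    facet_stagger: float = 1.5  # craniocaudal offset of pre/post facet centres
    zyg_height: float = 9.0  # facet centre above centrum axis
    zyg_lateral_offset: float = 5.5  # facet centre from midline
    # articulation
    gap: float | tuple | list = 2.0  # optimal joint spacing
    intercentra: CrescentSpec | None = None
    # bookkeeping
    damage: list = field(default_factory=list)  # [(vertebra ordinal, side)]
    sections: int = 32  # centrum revolve resolution
    seed: int = 0
    landmark_noise: float = 0.0  # mm, isotropic, off by default
    species: str = "synthetic"
    group: str = "NMS-grade"
    diaphragmatic_joint: int | None = None

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise ValueError("a column needs at least 2 vertebrae")
        if self.sections < 8 or self.sections % 4:
            raise ValueError(
                "sections must be a multiple of 4 and at least 8 to represent "
                "endplate extremes and facets"
            )
        for name in ("centrum_radius", "centrum_length", "facet_length", "facet_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for ang in np.atleast_1d(self.facet_angle):
            if not 0.0 <= float(ang) <= 90.0:
                raise ValueError("facet angles must lie in [0, 90] degrees")

    def _per_vertebra(self, value, k: int) -> float:
        if np.ndim(value) == 0:
            return float(value)
        return float(np.asarray(value, float)[k - 1])

    def facet_angle_at(self, k: int) -> float:
        return self._per_vertebra(self.facet_angle, k)

    def spine_height_at(self, k: int) -> float:
        return self._per_vertebra(self.spine_height, k)

    def gap_at(self, k: int) -> float:
        return self._per_vertebra(self.gap, k)

    @property
    def arch_top(self) -> float:
        return self.centrum_radius + self.arch_height


# ---------------------------------------------------------------------------
# primitives


def _box(center, extents) -> _tm.Trimesh:
    b = _tm.creation.box(extents=extents)
    b.apply_translation(center)
    return b


def _oriented_plate(center, x_len, normal, thickness, u_dir, width) -> _tm.Trimesh:
    """Rectangular plate: length along +X, ``thickness`` along ``normal``,
    ``width`` along ``u_dir``."""
    n = np.asarray(normal, float)
    u = np.asarray(u_dir, float)
    x = np.array([1.0, 0.0, 0.0])
    corners = []
    for sx in (-0.5, 0.5):
        for sn in (-0.5, 0.5):
            for su in (-0.5, 0.5):
                corners.append(
                    np.asarray(center)
                    + sx * x_len * x
                    + sn * thickness * n
                    + su * width * u
                )
    pts = np.array(corners)
    hull = _tm.convex.convex_hull(pts)
    return hull


def _centrum_mesh(spec: SyntheticColumnSpec) -> _tm.Trimesh:
    """Revolved solid of revolution: amphicoelous (both endplates dished) or
    procoelous (cranial cotyle, caudal spherical condyle)."""
    r = spec.centrum_radius
    L = spec.centrum_length
    d = spec.concavity_depth

    def dish(depth, n=6):
        # spherical dimple: radius R = (r^2 + depth^2) / (2 depth)
        if depth <= 0:
            return [(0.0, 0.0)] , 0.0
        R = (r * r + depth * depth) / (2.0 * depth)
        rho = np.linspace(0.0, r, n + 1)
        z = depth - (R - np.sqrt(np.maximum(R * R - rho * rho, 0.0)))
        return list(zip(rho, z)), depth

    prof = []
    cram, _ = dish(d)
    # cranial face: from axis (0, d) out to rim (r, 0)
    for rho, z in cram:
        prof.append((rho, z))
    # side wall with intermediate rings so edge lengths stay short
    n_side = max(2, int(np.ceil(L / (r / 3.0))))
    for t in np.linspace(0.0, 1.0, n_side + 1)[1:]:
        prof.append((r, t * L))
    if spec.centrum_type == "procoelous":
        depth = 0.5 * r
        Rc = (r * r + depth * depth) / (2.0 * depth)
        rho = np.linspace(r, 0.0, 9)
        z = L + depth - (Rc - np.sqrt(np.maximum(Rc * Rc - rho * rho, 0.0)))
        # convex condyle bulging caudally
        z = L + (depth - (Rc - np.sqrt(np.maximum(Rc * Rc - rho * rho, 0.0))))
        for rr, zz in zip(rho[1:], z[1:]):
            prof.append((rr, zz))
    else:
        for rho, z in reversed(cram[:-1]):
            prof.append((rho, L - z))
    profile = np.array(prof)
    m = _tm.creation.revolve(profile[:, ::1], sections=spec.sections)
    # revolve axis is Z; map to +X craniocaudal with +Y dorsal: (x,y,z)->(z,y,-x)
    T = np.array(
        [[0.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 0.0], [-1.0, 0.0, 0.0, 0.0], [0, 0, 0, 1.0]]
    )
    m.apply_transform(T)
    # elliptical endplate: scale the mediolateral axis
    if spec.endplate_aspect != 1.0:
        m.apply_scale([1.0, 1.0, spec.endplate_aspect])
    if m.volume < 0:
        m.invert()
    return m


def _facet_frames(angle_deg: float, side: str):
    """(normal, u) of a zygapophyseal facet plate.

    The prezygapophyseal facet faces dorsomedially; at 0 degrees it is
    horizontal (normal +Y), at 90 degrees parasagittal (normal points
    medially)."""
    phi = np.radians(angle_deg)
    sz = 1.0 if side == "left" else -1.0
    n = np.array([0.0, np.cos(phi), -sz * np.sin(phi)])
    u = np.cross(n, np.array([1.0, 0.0, 0.0]))
    u /= np.linalg.norm(u)
    return n, u


def generate_vertebra(
    spec: SyntheticColumnSpec, k: int
) -> tuple[_mesh.TriMesh, LandmarkSet]:
    """Build vertebra ordinal ``k`` (1-based) of a column specification.

    Returns a watertight multi-part solid and its analytic landmark set
    (local frame: cranial rim plane at x = 0). Deterministic given the spec
    seed.
    """
    r = spec.centrum_radius
    a = r * spec.endplate_aspect  # lateral half-width
    L = spec.centrum_length
    g = spec.gap_at(k)
    # facet orientation is a property of the articulation: the
    # prezygapophysis takes this vertebra's angle, the postzygapophysis the
    # NEXT vertebra's angle so facing facets at each joint are congruent
    phi_pre = spec.facet_angle_at(k)
    phi_post = spec.facet_angle_at(min(k + 1, spec.n_vertebrae))
    h_spine = spec.spine_height_at(k)
    arch_top = spec.arch_top

    parts = [_centrum_mesh(spec)]
    # neural arch: box resting on the centrum
    parts.append(
        _box(
            center=[L / 2.0, 0.5 * r + 0.5 * (arch_top - 0.5 * r), 0.0],
            extents=[0.6 * L, arch_top - 0.5 * r, spec.arch_width],
        )
    )
    if h_spine > 0:
        parts.append(
            _box(
                center=[L / 2.0, arch_top - 0.5 + 0.5 * (h_spine + 0.5), 0.0],
                extents=[spec.spine_thickness, h_spine + 0.5, spec.spine_thickness],
            )
        )

    damaged_sides = {side for (vk, side) in spec.damage if vk == k}
    points: dict[str, np.ndarray] = {}
    facets: dict[str, np.ndarray] = {}
    for face, x in (("cranial", 0.0), ("caudal", L)):
        points[f"{face}_endplate_dorsal"] = np.array([x, r, 0.0])
        points[f"{face}_endplate_ventral"] = np.array([x, -r, 0.0])
        points[f"{face}_endplate_left"] = np.array([x, 0.0, a])
        points[f"{face}_endplate_right"] = np.array([x, 0.0, -a])
    points["arch_apex"] = np.array([L / 2.0, arch_top, 0.0])

    # zygapophyseal plates. Facet contact is centred over each joint gap;
    # the prezygapophyseal facet of THIS vertebra articulates across the
    # cranial joint (gap centre at x = -g/2), the postzygapophyseal facet
    # across the caudal joint (gap centre at x = L + g/2). Pre and post
    # facets are staggered craniocaudally so the capsule locator pairs have
    # a finite neutral length.
    t_f = spec.facet_thickness
    c_f = spec.facet_clearance
    s_f = spec.facet_stagger
    for side in ("left", "right"):
        if side in damaged_sides:
            continue
        n, u = _facet_frames(phi_pre, side)
        sz = 1.0 if side == "left" else -1.0
        base = np.array([0.0, spec.zyg_height, sz * spec.zyg_lateral_offset])
        # prezygapophysis (articulates across joint k-1); the pre/post plate
        # pair is centred on the nominal zygapophysis position, the
        # postzygapophysis of the neighbour sitting dorsomedially
        g_pre = spec.gap_at(max(k - 1, 1))
        c_pre = base + np.array([-g_pre / 2.0 - s_f, 0.0, 0.0]) - n * (t_f + c_f) / 2.0
        parts.append(
            _oriented_plate(c_pre, spec.facet_length, n, t_f, u, spec.facet_width)
        )
        surf_pre = c_pre + n * (t_f / 2.0)
        points[f"prezyg_{side}_cranial"] = surf_pre + np.array([-spec.facet_length / 2, 0, 0])
        points[f"prezyg_{side}_caudal"] = surf_pre + np.array([+spec.facet_length / 2, 0, 0])
        facets[f"prezyg_{side}"] = np.array(
            [
                surf_pre + sx * spec.facet_length / 2 * np.array([1.0, 0, 0]) + su * spec.facet_width / 2 * u
                for sx, su in ((-1, -1), (1, -1), (1, 1), (-1, 1))
            ]
        )
        # postzygapophysis (articulates across joint k); sits on the
        # dorsomedial side of the next vertebra's prezygapophysis
        n, u = _facet_frames(phi_post, side)
        g_post = spec.gap_at(min(k, spec.n_vertebrae - 1))
        c_post = base + np.array([L + g_post / 2.0 + s_f, 0.0, 0.0]) + n * (t_f + c_f) / 2.0
        parts.append(
            _oriented_plate(c_post, spec.facet_length, n, t_f, u, spec.facet_width)
        )
        surf_post = c_post - n * (t_f / 2.0)
        points[f"postzyg_{side}_cranial"] = surf_post + np.array([-spec.facet_length / 2, 0, 0])
        points[f"postzyg_{side}_caudal"] = surf_post + np.array([+spec.facet_length / 2, 0, 0])
        facets[f"postzyg_{side}"] = np.array(
            [
                surf_post + sx * spec.facet_length / 2 * np.array([1.0, 0, 0]) + su * spec.facet_width / 2 * u
                for sx, su in ((-1, -1), (1, -1), (1, 1), (-1, 1))
            ]
        )

    condyle = None
    if spec.centrum_type == "procoelous":
        depth = 0.5 * r
        Rc = (r * r + depth * depth) / (2.0 * depth)
        cx = L + depth - Rc  # sphere centre on the axis
        rng_t = np.linspace(0.15, np.arcsin(min(r / Rc, 1.0)) - 0.05, 4)
        pts = []
        for t in rng_t:
            for ang in np.linspace(0, 2 * np.pi, 7)[:-1]:
                pts.append(
                    [
                        cx + Rc * np.cos(t),
                        Rc * np.sin(t) * np.cos(ang),
                        Rc * np.sin(t) * np.sin(ang) * spec.endplate_aspect,
                    ]
                )
        condyle = np.array(pts)

    if spec.landmark_noise > 0:
        rng = np.random.default_rng(spec.seed + 1000 * k)
        for key in points:
            points[key] = points[key] + rng.normal(0, spec.landmark_noise, 3)

    lms = LandmarkSet(
        points=points,
        centrum_length=L,
        endplate_area=float(np.pi * r * a),
        side_damage=(next(iter(damaged_sides)) if damaged_sides else "none"),
        facets=facets,
        condyle_points=condyle,
    )
    mesh = _mesh.TriMesh(parts=parts, label=f"{spec.species}_v{k}")
    return mesh, lms


def generate_intercentrum(spec: SyntheticColumnSpec, joint: int) -> _mesh.TriMesh:
    """Ventral crescent-like intercentrum of one joint, in the local frame
    of the ANTERIOR vertebra of that joint."""
    ic = spec.intercentra
    if ic is None:
        raise ValueError("spec has no intercentrum parameters")
    L = spec.centrum_length
    g = spec.gap_at(joint)
    r = spec.centrum_radius
    x0 = L - ic.lip
    x1 = L + g - ic.clearance  # caudal reach at the dorsal edge
    y0 = -r - 0.5  # slightly proud of the ventral rim
    y1 = y0 + ic.height
    tan_b = np.tan(np.radians(ic.wedge_angle))
    pts = []
    for z in (-ic.width / 2.0, ic.width / 2.0):
        pts += [
            [x0, y0, z],
            [x0, y1, z],
            # caudal face recedes ventrally: a ventroflexing posterior
            # endplate (whose lower half sweeps cranially) meets the whole
            # face almost simultaneously near the wedge angle
            [x1 - ic.height * tan_b, y0, z],
            [x1, y1, z],
        ]
    hull = _tm.convex.convex_hull(np.array(pts))
    return _mesh.TriMesh(parts=[hull], label=f"{spec.species}_ic{joint}")


def generate_column(
    spec: SyntheticColumnSpec, out_dir: str | Path | None = None
) -> ColumnModel:
    """Generate, assemble and (optionally) write a synthetic column.

    With ``out_dir`` the meshes (PLY), landmark sidecars and a ready-to-run
    YAML manifest are written to disk; the assembled in-memory column is
    returned either way.
    """
    vertebrae = []
    for k in range(1, spec.n_vertebrae + 1):
        mesh, lms = generate_vertebra(spec, k)
        vertebrae.append(Vertebra(name=f"v{k:02d}", mesh=mesh, landmarks=lms))

    gaps = [spec.gap_at(k) for k in range(1, spec.n_vertebrae)]
    intercentra = {}
    if spec.intercentra is not None:
        offset = 0.0
        for j in range(1, spec.n_vertebrae):
            ic = generate_intercentrum(spec, j)
            intercentra[j] = _mesh.rigid_translate(ic, [offset, 0.0, 0.0])
            offset += spec.centrum_length + gaps[j - 1]

    column = assemble_column(
        vertebrae,
        optimal_spacing=gaps,
        species=spec.species,
        group=spec.group,
        centrum_type=spec.centrum_type,
        diaphragmatic_joint=spec.diaphragmatic_joint,
        intercentra=intercentra,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        man = {
            "species": spec.species,
            "group": spec.group,
            "units": "mm",
            "centrum_type": spec.centrum_type,
            "optimal_spacing": gaps,
            "diaphragmatic_joint": spec.diaphragmatic_joint,
            "vertebrae": [],
            "intercentra": [],
        }
        for k, v in enumerate(vertebrae, start=1):
            mesh_name = f"{spec.species}_v{k:02d}.ply"
            lm_name = f"{spec.species}_v{k:02d}.landmarks.txt"
            _mesh.save_mesh(v.mesh, out_dir / mesh_name)
            _io.write_landmarks(v.landmarks, out_dir / lm_name)
            man["vertebrae"].append(
                {
                    "name": v.name,
                    "mesh": mesh_name,
                    "landmarks": lm_name,
                    "damage": v.landmarks.side_damage,
                }
            )
        for j, ic in intercentra.items():
            ic_name = f"{spec.species}_ic{j:02d}.ply"
            _mesh.save_mesh(ic, out_dir / ic_name)
            man["intercentra"].append({"joint": j, "mesh": ic_name})
        _io.write_manifest(man, out_dir / f"{spec.species}.manifest.yaml")
    return column


def spine_contact_angle(spec: SyntheticColumnSpec) -> float:
    """Analytic dorsiflexion angle at which adjacent neural-spine tips meet.

    Treats the spine (or, with no spine, the arch roof) top cranial corner
    of the posterior vertebra as a point rotating about the joint COR and
    finds where it reaches the caudal face plane of the anterior spine.
    Angles above 90 degrees mean the spines can never touch within a sweep.
    Returns the minimum over joints (degrees).
    """
    worst = 180.0
    for j in range(1, spec.n_vertebrae):
        g = spec.gap_at(j)
        D = (spec.centrum_length + g - spec.spine_thickness) / 2.0
        h_a = spec.arch_top + max(spec.spine_height_at(j), 0.0)
        h_p = spec.arch_top + max(spec.spine_height_at(j + 1), 0.0)
        # with unequal spines the first contact is near the shorter tip
        h = min(h_a, h_p)
        R = np.hypot(D, h)
        theta = np.degrees(np.arccos(-D / R) - np.arctan2(h, D))
        worst = min(worst, float(theta))
    return worst


# ---------------------------------------------------------------------------
# presets


PRESETS = ("mammal_like", "reptile_like", "cynodont_like", "sailback", "tuatara_like")


def preset(name: str, n_vertebrae: int = 8, seed: int = 0) -> SyntheticColumnSpec:
    """Named column morphologies echoing the comparative sample.

    * ``mammal_like`` — near-horizontal facets anteriorly, near-vertical
      posteriorly (sigmoid switch at mid-column = the diaphragmatic
      position), wide-flat centra. Anterior joints twist, posterior joints
      bend sagittally.
    * ``reptile_like`` — uniform oblique facets, tall-narrow centra;
      lateroflexion-dominant throughout.
    * ``cynodont_like`` — horizontal anterior facets with reduced posterior
      joint spacing (posterior lateral stabilization).
    * ``sailback`` — neural spines hyperelongate (x15) at mid-column.
    * ``tuatara_like`` — oblique facets with a ventral crescent
      intercentrum at every joint.
    """
    n = n_vertebrae
    mid = (n + 1) / 2.0
    if name == "mammal_like":
        # steep sigmoid: the facet orientation flips at the diaphragmatic
        # position, as in the mammalian pre-/post-diaphragmatic transition.
        # Joint k articulates with vertebra k+1's prezygapophyses, so the
        # last axially-mobile (horizontal-facet) joint is floor((n-1)/2).
        return SyntheticColumnSpec(
            n_vertebrae=n,
            facet_angle=sigmoid_profile(n, 5.0, 85.0, mid, rate=8.0),
            endplate_aspect=1.25,
            species="mammal_like",
            group="mammal",
            diaphragmatic_joint=(n - 1) // 2,
            seed=seed,
        )
    if name == "reptile_like":
        return SyntheticColumnSpec(
            n_vertebrae=n,
            facet_angle=70.0,
            endplate_aspect=0.85,
            species="reptile_like",
            group="reptile",
            seed=seed,
        )
    if name == "cynodont_like":
        gaps = np.full(n, 2.0)
        gaps[int(np.floor(mid)) :] = 1.2
        return SyntheticColumnSpec(
            n_vertebrae=n,
            facet_angle=sigmoid_profile(n, 5.0, 70.0, mid, rate=8.0),
            gap=gaps,
            species="cynodont_like",
            group="NMS-grade",
            seed=seed,
        )
    if name == "sailback":
        base = 12.0
        k = np.arange(1, n + 1)
        heights = base * (1.0 + 14.0 * np.exp(-(((k - mid) / (n / 4.0)) ** 2)))
        return SyntheticColumnSpec(
            n_vertebrae=n,
            spine_height=heights,
            facet_angle=45.0,
            species="sailback",
            group="NMS-grade",
            seed=seed,
        )
    if name == "tuatara_like":
        # roomier joints (larger gap, longer capsule pairs) let the bony
        # intercentrum stop express itself before the soft-tissue limits
        return SyntheticColumnSpec(
            n_vertebrae=n,
            facet_angle=45.0,
            gap=3.0,
            facet_stagger=2.5,
            intercentra=CrescentSpec(),
            species="tuatara_like",
            group="reptile",
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
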