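"""Articulated joint and column models.

Coordinate convention (right-handed, all inputs pre-oriented):

* +X craniocaudal, pointing caudally — axial rotation axis
* +Y dorsoventral, pointing dorsally — lateral bending axis
* +Z mediolateral, pointing to the anatomical left — sagittal bending axis

A joint is the articulation between an *anterior* and a *posterior*
vertebra. The posterior vertebra is the moving element: it is rotated about
the joint's centre of rotation (COR) during bending experiments. The COR is
the midpoint of the intervertebral space for amphicoelous/acoelous centra,
or the centre of a least-squares sphere fitted to the condyle for
procoelous centra. Joints are named after their anterior vertebra (joint k
connects vertebra k and vertebra k+1, 1-based).

Soft-tissue locator pairs span the joint at the endplate extremes (the
intervertebral disc) and at the zygapophyseal facet extremes (the capsular
ligaments); the bending engine limits the relative length change of each
pair.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import mesh as _mesh
from ._kernel import rotate_points

ENDPLATE_POSITIONS = ("dorsal", "ventral", "left", "right")
SIDES = ("left", "right")


class LandmarkError(ValueError):
    """Missing or invalid landmark data."""


class AssemblyError(RuntimeError):
    """A joint could not be assembled (e.g. interpenetrating at neutral)."""


@dataclass
class LandmarkSet:
    """Named anatomical points of one vertebra (mm).

    ``points`` must contain ``{cranial,caudal}_endplate_{dorsal,ventral,
    left,right}`` and ``arch_apex``; zygapophyseal extremes
    ``{pre,post}zyg_{left,right}_{cranial,caudal}`` may be absent on a
    damaged side. ``facets`` optionally holds (4, 3) corner arrays of the
    articular facet surfaces (keys like ``prezyg_left``) used for
    disarticulation checks; ``condyle_points`` optionally samples a
    procoelous condyle for sphere fitting.
    """

    points: dict[str, np.ndarray]
    centrum_length: float
    endplate_area: float
    side_damage: str = "none"
    facets: dict[str, np.ndarray] = field(default_factory=dict)
    condyle_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, float) for k, v in self.points.items()}
        for name, p in self.points.items():
            if p.shape != (3,) or not np.isfinite(p).all():
                raise LandmarkError(f"landmark {name!r} is not a finite 3D point")
        if not self.centrum_length > 0:
            raise LandmarkError("centrum_length must be positive")
        if not self.endplate_area > 0:
            raise LandmarkError("endplate_area must be positive")
        for face in ("cranial", "caudal"):
            for pos in ENDPLATE_POSITIONS:
                if f"{face}_endplate_{pos}" not in self.points:
                    raise LandmarkError(f"missing landmark {face}_endplate_{pos}")
        if "arch_apex" not in self.points:
            raise LandmarkError("missing landmark arch_apex")
        self.facets = {k: np.asarray(v, float) for k, v in self.facets.items()}

    def endplate_centroid(self, face: str) -> np.ndarray:
        """Centroid of the four extreme landmarks of one endplate face."""
        return np.mean(
            [self.points[f"{face}_endplate_{p}"] for p in ENDPLATE_POSITIONS], axis=0
        )

    def has_zyg(self, kind: str, side: str) -> bool:
        return (
            f"{kind}_{side}_cranial" in self.points
            and f"{kind}_{side}_caudal" in self.points
        )

    def translated(self, offset) -> "LandmarkSet":
        off = np.asarray(offset, float)
        return LandmarkSet(
            points={k: v + off for k, v in self.points.items()},
            centrum_length=self.centrum_length,
            endplate_area=self.endplate_area,
            side_damage=self.side_damage,
            facets={k: v + off for k, v in self.facets.items()},
            condyle_points=None if self.condyle_points is None else self.condyle_points + off,
        )

    def rotated(self, axis, angle_deg, center) -> "LandmarkSet":
        rot = lambda p: rotate_points(np.atleast_2d(p), axis, angle_deg, center)
        return LandmarkSet(
            points={k: rot(v)[0] for k, v in self.points.items()},
            centrum_length=self.centrum_length,
            endplate_area=self.endplate_area,
            side_damage=self.side_damage,
            facets={k: rot(v) for k, v in self.facets.items()},
            condyle_points=None
            if self.condyle_points is None
            else rot(self.condyle_points),
        )


@dataclass
class Vertebra:
    name: str
    mesh: _mesh.TriMesh
    landmarks: LandmarkSet

    def translated(self, offset) -> "Vertebra":
        return Vertebra(
            name=self.name,
            mesh=_mesh.rigid_translate(self.mesh, offset),
            landmarks=self.landmarks.translated(offset),
        )

    def rotated(self, axis, angle_deg, center) -> "Vertebra":
        return Vertebra(
            name=self.name,
            mesh=_mesh.rigid_rotate(self.mesh, axis, angle_deg, center),
            landmarks=self.landmarks.rotated(axis, angle_deg, center),
        )


@dataclass
class JointFrame:
    """COR plus right-handed orthonormal axis triad (X axial rotation,
    Y lateral bending, Z sagittal bending)."""

    cor: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.cor = np.asarray(self.cor, float)
        M = np.column_stack(
            [
                np.asarray(self.x_axis, float),
                np.asarray(self.y_axis, float),
                np.asarray(self.z_axis, float),
            ]
        )
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-9):
            raise ValueError("joint frame axes must be orthonormal")
        if np.linalg.det(M) < 0:
            raise ValueError("joint frame must be right-handed")
        self.x_axis, self.y_axis, self.z_axis = M[:, 0], M[:, 1], M[:, 2]

    @classmethod
    def anatomical(cls, cor) -> "JointFrame":
        return cls(
            cor=cor,
            x_axis=np.array([1.0, 0.0, 0.0]),
            y_axis=np.array([0.0, 1.0, 0.0]),
            z_axis=np.array([0.0, 0.0, 1.0]),
        )

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.x_axis, "y": self.y_axis, "z": self.z_axis}[name]


@dataclass
class LocatorPair:
    """A soft-tissue constraint spanning the joint."""

    anterior_point: np.ndarray
    posterior_point: np.ndarray
    tissue: str  # disc | capsule
    side: str  # left | right | mid
    name: str = ""

    @property
    def neutral_length(self) -> float:
        return float(np.linalg.norm(self.posterior_point - self.anterior_point))


@dataclass
class FacetPair:
    """Articulating zygapophyseal facet surfaces (4-corner polygons)."""

    postzyg_poly: np.ndarray  # on the anterior vertebra
    prezyg_poly: np.ndarray  # on the posterior vertebra
    normal: np.ndarray  # facet normal at neutral (projection direction)
    side: str


@dataclass
class JointModel:
    anterior: Vertebra
    posterior: Vertebra
    frame: JointFrame
    locator_pairs: list[LocatorPair]
    facet_pairs: list[FacetPair]
    spacing: float
    spacing_multiplier: float
    lever_sagittal: float
    lever_lateral: float
    centrum_area: float
    mean_centrum_length: float
    joint_index: int = 1

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise AssemblyError("joint spacing must be positive")
        if not (self.lever_sagittal > 0 and self.lever_lateral > 0):
            raise AssemblyError("lever arms must be positive")
        tissues = {p.tissue for p in self.locator_pairs}
        if "disc" not in tissues:
            raise AssemblyError("joint must carry disc locator pairs")

    @property
    def name(self) -> str:
        return f"joint_{self.joint_index}"


# ---------------------------------------------------------------------------
# COR placement


def place_cor_amphicoelous(
    anterior_landmarks: LandmarkSet, posterior_landmarks: LandmarkSet
) -> np.ndarray:
    """Midpoint of the intervertebral space between adjacent amphicoelous
    (or acoelous) centra: the midpoint of the facing endplate centroids."""
    a = anterior_landmarks.endplate_centroid("caudal")
    p = posterior_landmarks.endplate_centroid("cranial")
    if np.linalg.norm(p - a) < 1e-12:
        warnings.warn("zero intervertebral spacing: COR placed at the shared centroid")
    return 0.5 * (a + p)


def fit_sphere(points: np.ndarray):
    """Algebraic least-squares sphere fit.

    Returns ``(center, radius, rms)`` where rms is the root-mean-square
    radial residual. Raises on coplanar/collinear input (ill-conditioned).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 3:
        raise ValueError("need at least 4 three-dimensional points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    scale = np.ptp(pts, axis=0).max() or 1.0
    if rank < 4 or sv[-1] < 1e-9 * sv[0] * scale:
        raise LandmarkError("sphere fit is ill-conditioned (coplanar or collinear points)")
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(resid**2)))


def place_cor_procoelous(condyle_points: np.ndarray) -> np.ndarray:
    """Geometric centre of a sphere fitted to a procoelous condyle."""
    center, _, _ = fit_sphere(condyle_points)
    return center


# ---------------------------------------------------------------------------
# joint construction


def _disc_side(position: str) -> str:
    return position if position in SIDES else "mid"


def build_joint(
    anterior: Vertebra,
    posterior: Vertebra,
    optimal_spacing: float,
    spacing_multiplier: float = 1.0,
    centrum_type: str = "amphicoelous",
    joint_index: int = 1,
    check_interpenetration: bool = True,
) -> JointModel:
    """Assemble a joint from a pre-oriented vertebra pair.

    The posterior vertebra is translated along +X so the craniocaudal gap
    between the facing endplate centroids equals
    ``optimal_spacing * spacing_multiplier``; the COR, axis frame, locator
    pairs, facet pairs and lever arms are then derived from the landmarks.
    """
    if not optimal_spacing > 0:
        raise AssemblyError("optimal spacing must be positive")
    gap = optimal_spacing * spacing_multiplier
    a_cent = anterior.landmarks.endplate_centroid("caudal")
    p_cent = posterior.landmarks.endplate_centroid("cranial")
    shift = np.array([a_cent[0] + gap - p_cent[0], 0.0, 0.0])
    posterior = posterior.translated(shift)
    p_lms = posterior.landmarks
    a_lms = anterior.landmarks

    if centrum_type == "amphicoelous":
        cor = place_cor_amphicoelous(a_lms, p_lms)
    elif centrum_type == "procoelous":
        if a_lms.condyle_points is None:
            raise LandmarkError(
                f"procoelous joint {joint_index}: anterior vertebra has no condyle points"
            )
        cor = place_cor_procoelous(a_lms.condyle_points)
    else:
        raise ValueError(f"unknown centrum type {centrum_type!r}")

    pairs: list[LocatorPair] = []
    for pos in ENDPLATE_POSITIONS:
        pairs.append(
            LocatorPair(
                anterior_point=a_lms.points[f"caudal_endplate_{pos}"],
                posterior_point=p_lms.points[f"cranial_endplate_{pos}"],
                tissue="disc",
                side=_disc_side(pos),
                name=f"disc_{pos}",
            )
        )
    for side in SIDES:
        if a_lms.has_zyg("postzyg", side) and p_lms.has_zyg("prezyg", side):
            for ext in ("cranial", "caudal"):
                pairs.append(
                    LocatorPair(
                        anterior_point=a_lms.points[f"postzyg_{side}_{ext}"],
                        posterior_point=p_lms.points[f"prezyg_{side}_{ext}"],
                        tissue="capsule",
                        side=side,
                        name=f"capsule_{side}_{ext}",
                    )
                )

    facet_pairs: list[FacetPair] = []
    for side in SIDES:
        post_key, pre_key = f"postzyg_{side}", f"prezyg_{side}"
        if post_key in a_lms.facets and pre_key in p_lms.facets:
            pre = p_lms.facets[pre_key]
            n = np.cross(pre[1] - pre[0], pre[2] - pre[0])
            n = n / np.linalg.norm(n)
            facet_pairs.append(
                FacetPair(
                    postzyg_poly=a_lms.facets[post_key],
                    prezyg_poly=pre,
                    normal=n,
                    side=side,
                )
            )

    lever_sag = 0.5 * (
        np.linalg.norm(a_lms.points["arch_apex"] - cor)
        + np.linalg.norm(p_lms.points["arch_apex"] - cor)
    )
    lat_pts = [
        a_lms.points["caudal_endplate_left"],
        a_lms.points["caudal_endplate_right"],
        p_lms.points["cranial_endplate_left"],
        p_lms.points["cranial_endplate_right"],
    ]
    lever_lat = float(np.mean([np.linalg.norm(p - cor) for p in lat_pts]))

    joint = JointModel(
        anterior=anterior,
        posterior=posterior,
        frame=JointFrame.anatomical(cor),
        locator_pairs=pairs,
        facet_pairs=facet_pairs,
        spacing=gap,
        spacing_multiplier=spacing_multiplier,
        lever_sagittal=float(lever_sag),
        lever_lateral=lever_lat,
        centrum_area=0.5 * (a_lms.endplate_area + p_lms.endplate_area),
        mean_centrum_length=0.5 * (a_lms.centrum_length + p_lms.centrum_length),
        joint_index=joint_index,
    )
    if check_interpenetration and _mesh.first_contact(anterior.mesh, posterior.mesh):
        raise AssemblyError(
            f"joint {joint_index}: vertebrae interpenetrate at the neutral pose"
        )
    return joint


# ---------------------------------------------------------------------------
# columns


@dataclass
class ColumnModel:
    """An articulated vertebral column with per-joint models."""

    vertebrae: list[Vertebra]
    joints: list[JointModel]
    species: str = "unknown"
    group: str = "unknown"  # mammal | reptile | salamander | NMS-grade
    centrum_type: str = "amphicoelous"
    optimal_spacing: float | list[float] = 1.0
    diaphragmatic_joint: int | None = None  # mammals, 1-based joint index
    intercentra: dict[int, _mesh.TriMesh] = field(default_factory=dict)
    spacing_multiplier: float = 1.0

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def joint_spacing(self, joint_index: int) -> float:
        if isinstance(self.optimal_spacing, (int, float)):
            return float(self.optimal_spacing)
        return float(self.optimal_spacing[joint_index - 1])

    def damage(self) -> dict[int, str]:
        """Per-joint damaged side: a joint is damaged on a side when either
        adjacent vertebra is flagged on that side."""
        out = {}
        for j in self.joints:
            flags = {j.anterior.landmarks.side_damage, j.posterior.landmarks.side_damage}
            flags.discard("none")
            if len(flags) == 2:
                out[j.joint_index] = "both"
            elif flags:
                out[j.joint_index] = flags.pop()
            else:
                out[j.joint_index] = "none"
        return out


def assemble_column(
    vertebrae: list[Vertebra],
    optimal_spacing: float | list[float],
    spacing_multiplier: float = 1.0,
    species: str = "unknown",
    group: str = "unknown",
    centrum_type: str = "amphicoelous",
    diaphragmatic_joint: int | None = None,
    intercentra: dict[int, _mesh.TriMesh] | None = None,
    check_interpenetration: bool = True,
) -> ColumnModel:
    """Chain pre-oriented vertebrae into an articulated column.

    Vertebra k+1 is translated along +X so every inter-endplate gap equals
    the joint's optimal spacing times ``spacing_multiplier``.
    """
    if len(vertebrae) < 2:
        raise AssemblyError("a column needs at least two vertebrae")
    spacing_of = (
        (lambda k: float(optimal_spacing))
        if isinstance(optimal_spacing, (int, float))
        else (lambda k: float(optimal_spacing[k - 1]))
    )
    placed = [Vertebra(vertebrae[0].name, vertebrae[0].mesh.copy(), _copy.deepcopy(vertebrae[0].landmarks))]
    joints: list[JointModel] = []
    for k in range(1, len(vertebrae)):
        joint = build_joint(
            placed[-1],
            vertebrae[k],
            optimal_spacing=spacing_of(k),
            spacing_multiplier=spacing_multiplier,
            centrum_type=centrum_type,
            joint_index=k,
            check_interpenetration=check_interpenetration,
        )
        placed.append(joint.posterior)
        joints.append(joint)
    return ColumnModel(
        vertebrae=placed,
        joints=joints,
        species=species,
        group=group,
        centrum_type=centrum_type,
        optimal_spacing=optimal_spacing,
        diaphragmatic_joint=diaphragmatic_joint,
        intercentra=dict(intercentra or {}),
        spacing_multiplier=spacing_multiplier,
    )


def apply_joint_rotation(
    column: ColumnModel, joint_index: int, axis: str, angle_deg: float
) -> ColumnModel:
    """Pose a column by rotating everything caudal to one joint.

    All vertebrae, locators, facet polygons and CORs caudal to the named
    joint rotate rigidly about that joint's COR along its frame axis
    (``axis`` in {"x", "y", "z"}); cranial elements are untouched.
    """
    idx = [j.joint_index for j in column.joints]
    if joint_index not in idx:
        raise IndexError(f"no joint {joint_index} in column (joints {idx})")
    pivot_joint = column.joints[idx.index(joint_index)]
    cor = pivot_joint.frame.cor
    rot_axis = pivot_joint.frame.axis(axis)

    def rot_pt(p):
        return rotate_points(np.atleast_2d(p), rot_axis, angle_deg, cor)[0]

    new_verts: list[Vertebra] = []
    for i, v in enumerate(column.vertebrae):
        if i + 1 > joint_index:  # vertebra ordinals are 1-based
            new_verts.append(v.rotated(rot_axis, angle_deg, cor))
        else:
            new_verts.append(v)

    new_joints: list[JointModel] = []
    for j in column.joints:
        if j.joint_index < joint_index:
            new_joints.append(j)
            continue
        anterior = new_verts[j.joint_index - 1]
        posterior = new_verts[j.joint_index]
        if j.joint_index == joint_index:
            frame = j.frame  # pivot COR and axes stay put
            pairs = [
                LocatorPair(
                    anterior_point=p.anterior_point,
                    posterior_point=rot_pt(p.posterior_point),
                    tissue=p.tissue,
                    side=p.side,
                    name=p.name,
                )
                for p in j.locator_pairs
            ]
            facets = [
                FacetPair(
                    postzyg_poly=f.postzyg_poly,
                    prezyg_poly=rotate_points(f.prezyg_poly, rot_axis, angle_deg, cor),
                    normal=f.normal,
                    side=f.side,
                )
                for f in j.facet_pairs
            ]
        else:
            frame = JointFrame(
                cor=rot_pt(j.frame.cor),
                x_axis=rotate_points(j.frame.x_axis[None], rot_axis, angle_deg, [0, 0, 0])[0],
                y_axis=rotate_points(j.frame.y_axis[None], rot_axis, angle_deg, [0, 0, 0])[0],
                z_axis=rotate_points(j.frame.z_axis[None], rot_axis, angle_deg, [0, 0, 0])[0],
            )
            pairs = [
                LocatorPair(
                    anterior_point=rot_pt(p.anterior_point),
                    posterior_point=rot_pt(p.posterior_point),
                    tissue=p.tissue,
                    side=p.side,
                    name=p.name,
                )
                for p in j.locator_pairs
            ]
            facets = [
                FacetPair(
                    postzyg_poly=rotate_points(f.postzyg_poly, rot_axis, angle_deg, cor),
                    prezyg_poly=rotate_points(f.prezyg_poly, rot_axis, angle_deg, cor),
                    normal=rotate_points(f.normal[None], rot_axis, angle_deg, [0, 0, 0])[0],
                    side=f.side,
                )
                for f in j.facet_pairs
            ]
        new_joints.append(
            JointModel(
                anterior=anterior,
                posterior=posterior,
                frame=frame,
                locator_pairs=pairs,
                facet_pairs=facets,
                spacing=j.spacing,
                spacing_multiplier=j.spacing_multiplier,
                lever_sagittal=j.lever_sagittal,
                lever_lateral=j.lever_lateral,
                centrum_area=j.centrum_area,
                mean_centrum_length=j.mean_centrum_length,
                joint_index=j.joint_index,
            )
        )
    return ColumnModel(
        vertebrae=new_verts,
        joints=new_joints,
        species=column.species,
        group=column.group,
        centrum_type=column.centrum_type,
        optimal_spacing=column.optimal_spacing,
        diaphragmatic_joint=column.diaphragmatic_joint,
        intercentra=column.intercentra,
        spacing_multiplier=column.spacing_multiplier,
    )
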