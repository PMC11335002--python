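"""Analytic validation fixtures.

Joint constructions whose range of motion has a closed form, used to
validate the bending engine: flat-ended cylinder pairs (first bone contact
at 2 atan(g/(2r))) and pure locator-pair joints (strain = cos(theta/2) - 1
for a pair diametrically spanning the COR).
"""

from __future__ import annotations

import numpy as np
import trimesh

from .column import (
    FacetPair,
    JointFrame,
    JointModel,
    LandmarkSet,
    LocatorPair,
    Vertebra,
    build_joint,
)
from .mesh import TriMesh

def cylinder_mesh(radius: float, length: float, sections: int = 64) -> TriMesh:
    """Flat-ended cylinder spanning x in [0, length], axis +X."""
    cyl = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    T = np.array(
        [[0, 0, 1, 0], [0, 1, 0, 0], [-1, 0, 0, 0], [0, 0, 0, 1]], dtype=float
    )
    cyl.apply_transform(T)
    cyl.apply_translation([length / 2.0, 0, 0])
    if cyl.volume < 0:
        cyl.invert()
    return TriMesh(parts=[cyl], label="cylinder")


def cylinder_landmarks(radius: float, length: float) -> LandmarkSet:
    pts = {}
    for face, x in (("cranial", 0.0), ("caudal", length)):
        pts[f"{face}_endplate_dorsal"] = np.array([x, radius, 0.0])
        pts[f"{face}_endplate_ventral"] = np.array([x, -radius, 0.0])
        pts[f"{face}_endplate_left"] = np.array([x, 0.0, radius])
        pts[f"{face}_endplate_right"] = np.array([x, 0.0, -radius])
    pts["arch_apex"] = np.array([length / 2.0, radius + 1.0, 0.0])
    return LandmarkSet(
        points=pts,
        centrum_length=length,
        endplate_area=np.pi * radius**2,
        side_damage="none",
    )


def make_cylinder_joint(radius: float, gap: float, length: float = None) -> JointModel:
    """Joint between two flat-ended cylinders: first bone contact in sagittal
    or lateral bending occurs at the analytic angle 2*atan(gap/(2*radius))."""
    length = length or 2.0 * radius
    mesh = cylinder_mesh(radius, length)
    lms = cylinder_landmarks(radius, length)
    a = Vertebra("cyl_a", mesh, lms)
    p = Vertebra("cyl_b", mesh.copy(), lms)
    return build_joint(a, p, optimal_spacing=gap, check_interpenetration=False)


def _far_cube(center) -> TriMesh:
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    box.apply_translation(center)
    return TriMesh(parts=[box], label="anchor")


def _dummy_vertebra(name: str, center) -> Vertebra:
    c = np.asarray(center, float)
    pts = {}
    for face, dx in (("cranial", -0.4), ("caudal", 0.4)):
        pts[f"{face}_endplate_dorsal"] = c + [dx, 0.4, 0.0]
        pts[f"{face}_endplate_ventral"] = c + [dx, -0.4, 0.0]
        pts[f"{face}_endplate_left"] = c + [dx, 0.0, 0.4]
        pts[f"{face}_endplate_right"] = c + [dx, 0.0, -0.4]
    pts["arch_apex"] = c + [0.0, 0.6, 0.0]
    lms = LandmarkSet(points=pts, centrum_length=1.0, endplate_area=1.0)
    return Vertebra(name, _far_cube(c), lms)


def make_locator_joint(
    pairs: list[tuple],
    cor=(1.0, 0.0, 0.0),
    facet_pairs: list[FacetPair] | None = None,
) -> JointModel:
    """Joint whose only meaningful constraints are explicit locator pairs.

    ``pairs`` is a list of (anterior point, posterior point, tissue); the
    bone meshes are small distant cubes that never make contact.
    """
    cor = np.asarray(cor, float)
    locators = [
        LocatorPair(
            anterior_point=np.asarray(a, float),
            posterior_point=np.asarray(p, float),
            tissue=tissue,
            side="mid",
            name=f"{tissue}_{i}",
        )
        for i, (a, p, tissue) in enumerate(pairs)
    ]
    if not any(p.tissue == "disc" for p in locators):
        locators.append(
            LocatorPair(
                anterior_point=cor + [-500.0, 1000.0, 0.0],
                posterior_point=cor + [500.0, 1000.0, 0.0],
                tissue="disc",
                side="mid",
                name="disc_anchor",
            )
        )
    return JointModel(
        anterior=_dummy_vertebra("anchor_a", cor + [-200.0, 0.0, 0.0]),
        posterior=_dummy_vertebra("anchor_p", cor + [200.0, 0.0, 0.0]),
        frame=JointFrame.anatomical(cor),
        locator_pairs=locators,
        facet_pairs=facet_pairs or [],
        spacing=1.0,
        spacing_multiplier=1.0,
        lever_sagittal=1.0,
        lever_lateral=1.0,
        centrum_area=1.0,
        mean_centrum_length=1.0,
        joint_index=1,
    )


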