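"""Structure-removal experiments.

Paired columns differing only in one bony structure isolate its effect on
range of motion: neural spines can be truncated just above the vertebral
arch, and ventral intercentra can be merged into the anterior vertebra of
each joint or removed. Everything else — landmarks, CORs, locators, joint
spacing, lever arms — is identical between the two arms of a pair, so ROM
differences are attributable to contact geometry alone.
"""

from __future__ import annotations

import logging

import numpy as np

from . import mesh as _mesh
from .column import ColumnModel, Vertebra, assemble_column

logger = logging.getLogger(__name__)


def _reassemble(column: ColumnModel, vertebrae, intercentra) -> ColumnModel:
    return assemble_column(
        vertebrae,
        optimal_spacing=column.optimal_spacing,
        spacing_multiplier=column.spacing_multiplier,
        species=column.species,
        group=column.group,
        centrum_type=column.centrum_type,
        diaphragmatic_joint=column.diaphragmatic_joint,
        intercentra=intercentra,
        check_interpenetration=False,
    )


def remove_neural_spines(column: ColumnModel, cut_offset: float = 0.0) -> ColumnModel:
    """Truncate every neural spine just above the vertebral arch.

    Each vertebra's mesh is cut by a transverse (dorsoventral-normal) plane
    at its ``arch_apex`` height plus ``cut_offset`` (mm). Landmarks are NOT
    modified: lever arms and centrum metrics keep their original values so
    that paired experiments isolate the contact-geometry effect.
    """
    new_verts = []
    for v in column.vertebrae:
        apex = v.landmarks.points["arch_apex"]
        y_cut = apex[1] + cut_offset
        dorsal_rim = max(
            v.landmarks.points["cranial_endplate_dorsal"][1],
            v.landmarks.points["caudal_endplate_dorsal"][1],
        )
        if y_cut < dorsal_rim:
            raise ValueError(
                f"cut plane at y={y_cut:.3g} lies below the centrum of {v.name}"
            )
        cut = _mesh.cut_above_plane(v.mesh, [0.0, y_cut, 0.0], [0.0, 1.0, 0.0])
        cut.label = v.mesh.label
        new_verts.append(Vertebra(name=v.name, mesh=cut, landmarks=v.landmarks))
    return _reassemble(column, new_verts, column.intercentra)


def attach_intercentra(
    column: ColumnModel, mode: str = "merged", realign: bool = False
) -> ColumnModel:
    """Include or exclude intercentra in the bending model.

    ``merged``: each joint's intercentrum mesh is unioned with the anterior
    vertebra of that joint, so the posterior vertebra rotates against the
    combined object. ``absent``: intercentra are dropped entirely. With
    ``realign`` a displaced intercentrum is translated (no rotation or
    scaling) so it is centred under the intervertebral space with its
    dorsal margin at the ventral margin of the anterior centrum.
    """
    if mode not in ("merged", "absent"):
        raise ValueError("mode must be 'merged' or 'absent'")
    if mode == "absent":
        return _reassemble(column, column.vertebrae, {})

    new_verts = list(column.vertebrae)
    for joint in column.joints:
        k = joint.joint_index
        ic = column.intercentra.get(k)
        if ic is None:
            logger.warning("joint %d has no intercentrum mesh; skipped", k)
            continue
        anterior = new_verts[k - 1]
        if realign:
            lms = anterior.landmarks
            ventral = lms.points["caudal_endplate_ventral"]
            target_x = lms.endplate_centroid("caudal")[0] + joint.spacing / 2.0
            b = ic.bounds
            offset = np.array(
                [
                    target_x - 0.5 * (b[0][0] + b[1][0]),
                    ventral[1] - b[1][1],
                    0.0 - 0.5 * (b[0][2] + b[1][2]),
                ]
            )
            ic = _mesh.rigid_translate(ic, offset)
        merged = _mesh.merge_meshes(anterior.mesh, ic, label=anterior.mesh.label)
        new_verts[k - 1] = Vertebra(
            name=anterior.name, mesh=merged, landmarks=anterior.landmarks
        )
    return _reassemble(column, new_verts, column.intercentra)
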