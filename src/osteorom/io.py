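"""Column manifests and landmark sidecars (plain-text formats).

A column manifest is a YAML file listing, per vertebra, the mesh file and
landmark sidecar, plus column-level metadata (species, group, centrum type,
optimal joint spacing, region boundary, intercentrum meshes, units).

A landmark sidecar is a plain-text file with one named 3D point per line::

    arch_apex 10.0 17.0 0.0
    cranial_endplate_dorsal 0.0 10.0 0.0
    ...

and metadata lines starting with ``@``::

    @centrum_length 20.0
    @endplate_area 314.159
    @side_damage none
    @facet prezyg_left x1 y1 z1 x2 y2 z2 x3 y3 z3 x4 y4 z4
    @condyle x y z
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import mesh as _mesh
from .column import ColumnModel, LandmarkSet, Vertebra, assemble_column

_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def write_landmarks(lms: LandmarkSet, path) -> None:
    lines = ["# osteorom landmark sidecar (mm)"]
    for name in sorted(lms.points):
        x, y, z = lms.points[name]
        lines.append(f"{name} {x:.9g} {y:.9g} {z:.9g}")
    lines.append(f"@centrum_length {lms.centrum_length:.9g}")
    lines.append(f"@endplate_area {lms.endplate_area:.9g}")
    lines.append(f"@side_damage {lms.side_damage}")
    for key in sorted(lms.facets):
        coords = " ".join(f"{v:.9g}" for v in np.asarray(lms.facets[key]).ravel())
        lines.append(f"@facet {key} {coords}")
    if lms.condyle_points is not None:
        for p in lms.condyle_points:
            lines.append(f"@condyle {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks(path, scale: float = 1.0) -> LandmarkSet:
    points: dict[str, np.ndarray] = {}
    meta: dict[str, str] = {"side_damage": "none"}
    facets: dict[str, np.ndarray] = {}
    condyle: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if tok[0] == "@facet":
            vals = np.array([float(v) for v in tok[2:]], float)
            facets[tok[1]] = vals.reshape(-1, 3) * scale
        elif tok[0] == "@condyle":
            condyle.append([float(v) * scale for v in tok[1:4]])
        elif tok[0].startswith("@"):
            meta[tok[0][1:]] = tok[1]
        else:
            points[tok[0]] = np.array([float(v) for v in tok[1:4]]) * scale
    return LandmarkSet(
        points=points,
        centrum_length=float(meta["centrum_length"]) * scale,
        endplate_area=float(meta["endplate_area"]) * scale**2,
        side_damage=meta.get("side_damage", "none"),
        facets=facets,
        condyle_points=np.asarray(condyle) if condyle else None,
    )


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_column(
    manifest_path,
    spacing_multiplier: float = 1.0,
    check_interpenetration: bool = True,
) -> ColumnModel:
    """Load and assemble a column described by a manifest file."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    man = yaml.safe_load(manifest_path.read_text())
    scale = _UNIT_SCALE[man.get("units", "mm")]

    vertebrae = []
    for i, rec in enumerate(man["vertebrae"], start=1):
        mesh = _mesh.load_mesh(root / rec["mesh"], label=f"vertebra_{i}")
        if scale != 1.0:
            for p in mesh.parts:
                p.vertices = p.vertices * scale
            mesh._grid_cache.clear()
        lms = read_landmarks(root / rec["landmarks"], scale=scale)
        if rec.get("damage", "none") != "none":
            lms.side_damage = rec["damage"]
        vertebrae.append(Vertebra(name=rec.get("name", f"vertebra_{i}"), mesh=mesh, landmarks=lms))

    intercentra = {}
    for rec in man.get("intercentra", []) or []:
        ic = _mesh.load_mesh(root / rec["mesh"], label=f"intercentrum_{rec['joint']}")
        if scale != 1.0:
            for p in ic.parts:
                p.vertices = p.vertices * scale
            ic._grid_cache.clear()
        intercentra[int(rec["joint"])] = ic

    spacing = man["optimal_spacing"]
    if isinstance(spacing, list):
        spacing = [float(s) * scale for s in spacing]
    else:
        spacing = float(spacing) * scale

    return assemble_column(
        vertebrae,
        optimal_spacing=spacing,
        spacing_multiplier=spacing_multiplier,
        species=man.get("species", "unknown"),
        group=man.get("group", "unknown"),
        centrum_type=man.get("centrum_type", "amphicoelous"),
        diaphragmatic_joint=man.get("diaphragmatic_joint"),
        intercentra=intercentra,
        check_interpenetration=check_interpenetration,
    )
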