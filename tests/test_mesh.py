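"""Geometry substrate: I/O, rigid transforms, overlap, merge, cut."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from osteorom.mesh import (
    EmptyCutError,
    MeshError,
    TriMesh,
    cut_above_plane,
    first_contact,
    intersection_volume,
    load_mesh,
    merge_meshes,
    overlap_fraction,
    rigid_rotate,
    rigid_translate,
    save_mesh,
)


@pytest.mark.parametrize("ext", ["obj", "ply", "stl"])
def test_load_save_roundtrip(tmp_path, unit_cube, ext):
    path = tmp_path / f"cube.{ext}"
    save_mesh(unit_cube, path)
    loaded = load_mesh(path)
    assert loaded.is_watertight
    assert loaded.volume == pytest.approx(1.0, rel=1e-9)
    # a second round trip is lossless in counts
    path2 = tmp_path / f"cube2.{ext}"
    save_mesh(loaded, path2)
    again = load_mesh(path2)
    assert len(again.vertices) == len(loaded.vertices)
    assert len(again.faces) == len(loaded.faces)


def test_load_degenerate_mesh_errors(tmp_path):
    bad = tmp_path / "bad.obj"
    bad.write_text("v 0 0 0\nv 1 0 0\nv 2 0 0\nf 1 2 3\n")
    with pytest.raises(MeshError):
        load_mesh(bad)
    missing = tmp_path / "nope.obj"
    with pytest.raises(MeshError):
        load_mesh(missing)


class TestRigidRotate:
    def test_identity(self, unit_cube):
        out = rigid_rotate(unit_cube, [0, 0, 1], 0.0, [5, 5, 5])
        assert np.allclose(out.vertices, unit_cube.vertices)

    def test_quarter_turn_permutes_cube_vertices(self, unit_cube):
        out = rigid_rotate(unit_cube, [0, 0, 1], 90.0, [0, 0, 0])
        orig = {tuple(np.round(v, 9)) for v in unit_cube.vertices}
        new = {tuple(np.round(v, 9)) for v in out.vertices}
        assert orig == new

    def test_closed_form_point(self):
        tri = TriMesh.from_arrays(
            [[2, 0, 0], [2, 1e-3, 0], [2, 0, 1e-3]], [[0, 1, 2]]
        )
        out = rigid_rotate(tri, [0, 0, 1], 120.0, [1, 0, 0])
        assert np.allclose(out.vertices[0], [0.5, np.sqrt(3) / 2, 0.0], atol=1e-12)

    @given(
        angle=st.floats(-360.0, 360.0),
        axis=st.tuples(
            st.floats(-1, 1), st.floats(-1, 1), st.floats(0.1, 1)
        ),
        center=st.tuples(
            st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)
        ),
    )
    @settings(max_examples=25, deadline=None)
    def test_volume_and_distances_conserved(self, angle, axis, center):
        mesh = TriMesh(parts=[trimesh.creation.icosphere(1, radius=3.0)])
        out = rigid_rotate(mesh, list(axis), angle, list(center))
        assert out.volume == pytest.approx(mesh.volume, rel=1e-9)
        d0 = np.linalg.norm(mesh.vertices[0] - mesh.vertices[5])
        d1 = np.linalg.norm(out.vertices[0] - out.vertices[5])
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_zero_axis_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            rigid_rotate(unit_cube, [0, 0, 0], 10.0, [0, 0, 0])


class TestOverlap:
    def test_disjoint_is_zero(self, unit_cube):
        far = rigid_translate(unit_cube, [5, 0, 0])
        assert overlap_fraction(unit_cube, far) == 0.0

    def test_identical_is_one(self, unit_cube):
        assert overlap_fraction(unit_cube, unit_cube.copy(), pitch=0.05) == 1.0

    def test_null_rotation_is_exactly_one(self, unit_cube):
        rot = rigid_rotate(unit_cube, [0, 1, 0], 0.0, [3, 3, 3])
        assert overlap_fraction(unit_cube, rot, pitch=0.05) == 1.0

    @pytest.mark.parametrize("offset", [0.25, 0.5, 0.75])
    def test_analytic_box_offsets(self, unit_cube, offset):
        other = rigid_translate(unit_cube, [offset, 0, 0])
        # pitch commensurate with the offsets so cell centres avoid faces
        frac = overlap_fraction(unit_cube, other, pitch=0.025)
        assert frac == pytest.approx(1.0 - offset, abs=1e-9)

    def test_symmetry_in_arguments(self, unit_cube):
        other = rigid_translate(unit_cube, [0.3, 0.2, 0.1])
        f1 = overlap_fraction(unit_cube, other, pitch=0.04)
        f2 = overlap_fraction(other, unit_cube, pitch=0.04)
        assert f1 == f2

    def test_grid_matches_analytic_box_pairs_within_2pct(self, unit_cube):
        # pitch = 1/50 of the minimum box edge
        for off in ([0.4, 0.16, 0.0], [0.7, 0.0, 0.3]):
            other = rigid_translate(unit_cube, off)
            exact = np.prod([max(0.0, 1.0 - abs(o)) for o in off])
            got = intersection_volume(unit_cube, other, pitch=1 / 50)
            assert got == pytest.approx(exact, rel=0.02)

    def test_first_contact_detects_thin_slivers(self, unit_cube):
        # penetration far below any grid pitch
        apart = rigid_translate(unit_cube, [1.0 + 1e-4, 0, 0])
        touching = rigid_translate(unit_cube, [1.0 - 1e-4, 0, 0])
        assert not first_contact(unit_cube, apart)
        assert first_contact(unit_cube, touching)

    def test_area_normalization_switch(self, unit_cube):
        other = rigid_translate(unit_cube, [0.5, 0, 0])
        frac = overlap_fraction(unit_cube, other, normalization="mean_area", pitch=0.02)
        assert frac == pytest.approx(0.5 / 6.0, rel=1e-6)  # 0.5 mm3 over 6 mm2


class TestMergeAndCut:
    def test_merge_with_empty_is_identity(self, unit_cube):
        merged = merge_meshes(unit_cube, TriMesh.empty())
        assert merged.volume == pytest.approx(unit_cube.volume, rel=1e-12)

    def test_merge_disjoint_adds_volumes(self, unit_cube):
        far = rigid_translate(unit_cube, [3, 0, 0])
        assert merge_meshes(unit_cube, far).volume == pytest.approx(2.0, rel=1e-12)

    def test_merge_overlapping_inclusion_exclusion(self, unit_cube):
        other = rigid_translate(unit_cube, [0.5, 0, 0])
        union = merge_meshes(unit_cube, other).union_volume(pitch=0.02)
        assert union == pytest.approx(1.5, abs=1e-9)

    def test_merged_union_overlap_probe(self, unit_cube):
        # overlap against a probe equals that of the union of the inputs
        other = rigid_translate(unit_cube, [0.5, 0, 0])
        merged = merge_meshes(unit_cube, other)
        probe = rigid_translate(unit_cube, [1.0, 0, 0])
        inter = intersection_volume(merged, probe, pitch=0.02)
        assert inter == pytest.approx(0.5, abs=1e-6)

    def test_cut_above_mesh_is_noop(self, unit_cube):
        out = cut_above_plane(unit_cube, [0, 0, 2.0], [0, 0, 1])
        assert out.volume == pytest.approx(1.0, rel=1e-12)

    def test_cut_half_cube(self, unit_cube):
        out = cut_above_plane(unit_cube, [0, 0, 0.0], [0, 0, 1])
        assert out.is_watertight
        assert out.volume == pytest.approx(0.5, rel=1e-9)

    def test_cut_cylinder_recapped(self):
        cyl = TriMesh(parts=[trimesh.creation.cylinder(radius=10, height=20, sections=64)])
        out = cut_above_plane(cyl, [0, 0, 5.0], [0, 0, 1])
        assert out.is_watertight
        # 64-gon cross-section area correction
        poly = 64 / (2 * np.pi) * np.sin(2 * np.pi / 64)
        assert out.volume == pytest.approx(np.pi * 100 * 15 * poly, rel=1e-6)

    def test_cut_below_mesh_errors(self, unit_cube):
        with pytest.raises(EmptyCutError):
            cut_above_plane(unit_cube, [0, 0, -2.0], [0, 0, 1])
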