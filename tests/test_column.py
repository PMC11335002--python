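"""Joint and column construction: COR placement, frames, locators,
hierarchical kinematics."""

import numpy as np
import pytest

from osteorom.column import (
    JointFrame,
    LandmarkError,
    LandmarkSet,
    apply_joint_rotation,
    build_joint,
    fit_sphere,
    place_cor_amphicoelous,
    place_cor_procoelous,
)
from osteorom.synthetic import SyntheticColumnSpec, generate_column, generate_vertebra
from osteorom._kernel import rotate_points


def _landmarks_at(x0: float, r: float = 5.0, length: float = 10.0) -> LandmarkSet:
    pts = {}
    for face, x in (("cranial", x0), ("caudal", x0 + length)):
        pts[f"{face}_endplate_dorsal"] = np.array([x, r, 0.0])
        pts[f"{face}_endplate_ventral"] = np.array([x, -r, 0.0])
        pts[f"{face}_endplate_left"] = np.array([x, 0.0, r])
        pts[f"{face}_endplate_right"] = np.array([x, 0.0, -r])
    pts["arch_apex"] = np.array([x0 + length / 2, r + 2.0, 0.0])
    return LandmarkSet(points=pts, centrum_length=length, endplate_area=np.pi * r * r)


class TestCorPlacement:
    def test_amphicoelous_midpoint(self):
        a = _landmarks_at(0.0)
        p = _landmarks_at(12.0)
        cor = place_cor_amphicoelous(a, p)
        assert np.allclose(cor, [11.0, 0.0, 0.0])  # midpoint of x=10 and x=12

    def test_coincident_centroids_warn(self):
        a = _landmarks_at(0.0)
        p = _landmarks_at(10.0)  # cranial face exactly at the caudal face
        with pytest.warns(UserWarning, match="zero intervertebral spacing"):
            cor = place_cor_amphicoelous(a, p)
        assert np.allclose(cor, [10.0, 0.0, 0.0])

    def test_sphere_fit_exact(self):
        rng = np.random.default_rng(42)
        center, radius = np.array([3.0, -1.0, 2.0]), 5.0
        u = rng.normal(size=(100, 3))
        pts = center + radius * u / np.linalg.norm(u, axis=1, keepdims=True)
        assert np.allclose(place_cor_procoelous(pts), center, atol=1e-6)
        c, r, rms = fit_sphere(pts)
        assert r == pytest.approx(radius, abs=1e-9)
        assert rms < 1e-9

    def test_sphere_fit_with_noise(self):
        rng = np.random.default_rng(7)
        center, radius = np.array([3.0, -1.0, 2.0]), 5.0
        u = rng.normal(size=(100, 3))
        pts = center + radius * u / np.linalg.norm(u, axis=1, keepdims=True)
        pts = pts + rng.normal(0.0, 0.05, pts.shape)
        assert np.linalg.norm(place_cor_procoelous(pts) - center) < 0.05

    def test_sphere_fit_coplanar_errors(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(LandmarkError):
            place_cor_procoelous(pts)


class TestJointFrame:
    def test_orthonormal_right_handed(self, default_joint):
        f = default_joint.frame
        M = np.column_stack([f.x_axis, f.y_axis, f.z_axis])
        assert np.allclose(M.T @ M, np.eye(3), atol=1e-9)
        assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_frames_rejected(self):
        with pytest.raises(ValueError):
            JointFrame(cor=[0, 0, 0], x_axis=[1, 0, 0], y_axis=[1, 0, 0], z_axis=[0, 0, 1])
        with pytest.raises(ValueError):  # left-handed
            JointFrame(cor=[0, 0, 0], x_axis=[1, 0, 0], y_axis=[0, 1, 0], z_axis=[0, 0, -1])


class TestBuildJoint:
    def test_gap_equals_spacing(self):
        spec = SyntheticColumnSpec(n_vertebrae=2)
        col = generate_column(spec)
        j = col.joints[0]
        gap = (
            j.posterior.landmarks.endplate_centroid("cranial")[0]
            - j.anterior.landmarks.endplate_centroid("caudal")[0]
        )
        assert gap == pytest.approx(spec.gap_at(1), abs=1e-9)

    def test_multiplier_scales_gap_linearly(self):
        spec = SyntheticColumnSpec(n_vertebrae=2)
        mesh, lms = generate_vertebra(spec, 1)
        from osteorom.column import Vertebra

        a = Vertebra("a", mesh, lms)
        p = Vertebra("b", mesh.copy(), lms)
        j1 = build_joint(a, p, optimal_spacing=2.0, spacing_multiplier=1.0)
        j2 = build_joint(a, p, optimal_spacing=2.0, spacing_multiplier=1.1)
        assert j2.spacing == pytest.approx(1.1 * j1.spacing, rel=1e-12)

    def test_lever_is_cor_to_arch_apex_distance(self):
        a = _landmarks_at(0.0)
        p = _landmarks_at(12.0)
        # both arch apexes sit 20 above their centrum midpoints
        a.points["arch_apex"] = np.array([11.0, 20.0, 0.0])
        p.points["arch_apex"] = np.array([11.0, 20.0, 0.0])
        from osteorom.column import Vertebra
        from osteorom.validation import cylinder_mesh

        mesh = cylinder_mesh(5.0, 10.0)
        j = build_joint(
            Vertebra("a", mesh, a),
            Vertebra("p", cylinder_mesh(5.0, 10.0), p.translated([-12.0, 0, 0])),
            optimal_spacing=2.0,
            check_interpenetration=False,
        )
        assert j.lever_sagittal == pytest.approx(20.0, abs=1e-9)

    def test_locator_pairs_span_disc_and_capsule(self, default_joint):
        tissues = {p.tissue for p in default_joint.locator_pairs}
        assert tissues == {"disc", "capsule"}
        # 4 disc pairs + 2 sides x 2 extremes capsule pairs
        assert len(default_joint.locator_pairs) == 8


class TestHierarchy:
    def test_zero_rotation_is_identity(self, default_column):
        posed = apply_joint_rotation(default_column, 1, "z", 0.0)
        for v0, v1 in zip(default_column.vertebrae, posed.vertebrae):
            assert np.allclose(v0.mesh.vertices, v1.mesh.vertices)

    def test_caudal_vertebra_rotates_about_cor(self, default_column):
        cor = default_column.joints[0].frame.cor
        posed = apply_joint_rotation(default_column, 1, "z", 10.0)
        v3 = default_column.vertebrae[2].mesh.vertices
        expected = rotate_points(v3, [0, 0, 1], 10.0, cor)
        assert np.allclose(posed.vertebrae[2].mesh.vertices, expected, atol=1e-9)
        # cranial vertebra fixed
        assert np.allclose(
            posed.vertebrae[0].mesh.vertices, default_column.vertebrae[0].mesh.vertices
        )

    def test_rotation_inverse_restores_pose(self, default_column):
        posed = apply_joint_rotation(default_column, 2, "y", 7.5)
        restored = apply_joint_rotation(posed, 2, "y", -7.5)
        for v0, v1 in zip(default_column.vertebrae, restored.vertebrae):
            assert np.allclose(v0.mesh.vertices, v1.mesh.vertices, atol=1e-9)

    def test_forward_kinematics_matches_explicit_oracle(self):
        col = generate_column(SyntheticColumnSpec(n_vertebrae=5))
        rotations = [(1, "z", 8.0), (3, "y", -6.0), (4, "x", 5.0)]
        posed = col
        for j, ax, ang in rotations:
            posed = apply_joint_rotation(posed, j, ax, ang)

        # independent oracle: replay the rigid maps sequentially on the raw
        # points, tracking how each pivot COR and axis move under earlier
        # rotations in the chain
        axes = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}
        for vi, vert in enumerate(col.vertebrae, start=1):
            pts = vert.mesh.vertices.copy()
            cors = {j: col.joints[j - 1].frame.cor.copy() for j, _, _ in rotations}
            axs = {(j, ax): axes[ax].copy() for j, ax, _ in rotations}
            for j, ax, ang in rotations:
                if vi > j:
                    pts = rotate_points(pts, axs[(j, ax)], ang, cors[j])
                # every pivot caudal to j also moves
                for j2, ax2, _ in rotations:
                    if j2 > j:
                        cors[j2] = rotate_points(cors[j2][None], axs[(j, ax)], ang, cors[j])[0]
                        axs[(j2, ax2)] = rotate_points(
                            axs[(j2, ax2)][None], axs[(j, ax)], ang, [0, 0, 0]
                        )[0]
            assert np.allclose(posed.vertebrae[vi - 1].mesh.vertices, pts, atol=1e-8)

    def test_unknown_joint_errors(self, default_column):
        with pytest.raises(IndexError):
            apply_joint_rotation(default_column, 99, "z", 1.0)


def test_mirror_symmetry_maps_left_to_right():
    """Mirroring through the sagittal plane swaps left/right locators and
    preserves all pair lengths."""
    col = generate_column(SyntheticColumnSpec(n_vertebrae=2))
    j = col.joints[0]
    by_name = {p.name: p for p in j.locator_pairs}
    for ext in ("cranial", "caudal"):
        left = by_name[f"capsule_left_{ext}"]
        right = by_name[f"capsule_right_{ext}"]
        flip = np.array([1.0, 1.0, -1.0])
        assert np.allclose(left.anterior_point * flip, right.anterior_point)
        assert np.allclose(left.posterior_point * flip, right.posterior_point)
        assert left.neutral_length == pytest.approx(right.neutral_length, rel=1e-12)


def test_landmark_validation():
    with pytest.raises(LandmarkError):
        LandmarkSet(points={"arch_apex": np.array([0.0, 0, 0])}, centrum_length=1, endplate_area=1)
    lms = _landmarks_at(0.0)
    with pytest.raises(LandmarkError):
        LandmarkSet(points=lms.points, centrum_length=-1, endplate_area=1)
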