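"""Bending engine: constraint evaluation, sweeps, the factorial grid."""

import numpy as np
import pandas as pd
import pytest

from osteorom.bending import (
    BendingConfig,
    DIRECTIONS,
    VariantGrid,
    detect_disarticulation,
    evaluate_constraints,
    run_experiment,
    sweep_direction,
)
from osteorom.column import FacetPair
from osteorom.synthetic import SyntheticColumnSpec, generate_column
from osteorom.validation import make_cylinder_joint, make_locator_joint

STRAIN_OFF = 1e9


class TestConstraintEvaluation:
    def test_neutral_pose_is_clean(self, default_joint):
        rep = evaluate_constraints(default_joint, "dorsoflexion", 0.0)
        assert rep.worst_disc_strain == 0.0
        assert rep.worst_capsule_strain == 0.0
        assert rep.violated == set()
        assert not rep.disarticulated

    def test_locator_strain_closed_form(self):
        # pair a=(0,0,0), COR=(1,0,0), p=(2,0,0): distance = 2 cos(theta/2)
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        for theta in (20.0, 60.0, 90.0):
            rep = evaluate_constraints(joint, "dorsoflexion", theta)
            assert rep.worst_disc_strain == pytest.approx(
                np.cos(np.radians(theta / 2)) - 1.0, abs=1e-9
            )
        rep60 = evaluate_constraints(joint, "dorsoflexion", 60.0)
        assert rep60.worst_disc_strain == pytest.approx(-0.1340, abs=1e-4)

    def test_violation_threshold_is_strict(self):
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        # strain passes allowance exactly at theta = 2 acos(1 - a)
        a = 0.2
        theta_star = np.degrees(2 * np.arccos(1 - a))
        cfg = BendingConfig(strain_allowance=a)
        below = evaluate_constraints(joint, "dorsoflexion", theta_star - 1e-6, cfg)
        above = evaluate_constraints(joint, "dorsoflexion", theta_star + 1e-6, cfg)
        assert below.violated == set()
        assert above.violated == {"disc"}


class TestSweeps:
    def test_strain_fixture_rom_closed_form(self):
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        cfg = BendingConfig(strain_allowance=0.10)
        res = sweep_direction(joint, "dorsoflexion", cfg)
        # theta* = 2 acos(0.9) = 51.68 deg -> last clean step 51.5
        assert res.rom == 51.5
        assert res.limiting_constraint == "disc"

    @pytest.mark.parametrize(
        "allowance", [0.05, 0.10, 0.20], ids=["a05", "a10", "a20"]
    )
    def test_strain_rom_general_closed_form(self, allowance):
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        cfg = BendingConfig(strain_allowance=allowance)
        res = sweep_direction(joint, "ventroflexion", cfg)
        theta_star = np.degrees(2 * np.arccos(1 - allowance))
        assert res.rom == np.floor(theta_star / 0.5) * 0.5

    def test_unconstrained_joint_caps_at_90(self):
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        cfg = BendingConfig(strain_allowance=STRAIN_OFF)
        res = sweep_direction(joint, "left_axial", cfg)
        assert res.rom == 90.0
        assert res.limiting_constraint == "cap"

    def test_cylinder_contact_oracle(self):
        joint = make_cylinder_joint(radius=10.0, gap=2.0)
        cfg = BendingConfig(intersection_threshold=0.0, strain_allowance=STRAIN_OFF, pitch=0.8)
        res = sweep_direction(joint, "dorsoflexion", cfg)
        # analytic contact at 2 atan(g / 2r) = 11.42 deg
        assert res.rom == 11.0
        assert res.limiting_constraint == "bone"

    def test_spacing_multiplier_monotone_on_cylinders(self):
        cfg = BendingConfig(intersection_threshold=0.0, strain_allowance=STRAIN_OFF, pitch=0.8)
        roms = []
        for mult in (0.9, 1.0, 1.1):
            joint = make_cylinder_joint(radius=10.0, gap=2.0 * mult)
            roms.append(sweep_direction(joint, "ventroflexion", cfg).rom)
        assert roms[0] <= roms[1] <= roms[2]
        assert roms[0] < roms[2]

    def test_neutral_violation_gives_zero_rom(self):
        import trimesh
        from osteorom.mesh import TriMesh, rigid_translate

        # interpenetrating boxes assembled directly (build_joint would refuse)
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        box = TriMesh(parts=[trimesh.creation.box(extents=[2, 2, 2])])
        joint.anterior.mesh = box
        joint.posterior.mesh = rigid_translate(box, [1.0, 0, 0])
        with pytest.warns(UserWarning, match="neutral"):
            res = sweep_direction(joint, "dorsoflexion", BendingConfig())
        assert res.rom == 0.0
        assert res.limiting_constraint == "bone"

    def test_bilateral_symmetry_left_equals_right(self, default_joint):
        cfg = BendingConfig()
        for left, right in (
            ("left_lateroflexion", "right_lateroflexion"),
            ("left_axial", "right_axial"),
        ):
            rl = sweep_direction(default_joint, left, cfg)
            rr = sweep_direction(default_joint, right, cfg)
            assert rl.rom == rr.rom
            assert rl.limiting_constraint == rr.limiting_constraint

    def test_monotone_in_threshold_and_allowance(self, default_joint):
        grid = VariantGrid()
        for direction in ("dorsoflexion", "left_axial"):
            roms_thr = [
                sweep_direction(
                    default_joint, direction, BendingConfig(intersection_threshold=t)
                ).rom
                for t in grid.intersection_thresholds
            ]
            assert roms_thr == sorted(roms_thr)
            roms_allow = [
                sweep_direction(
                    default_joint, direction, BendingConfig(strain_allowance=a)
                ).rom
                for a in grid.strain_allowances
            ]
            assert roms_allow == sorted(roms_allow)


class TestDisarticulation:
    @staticmethod
    def _facet_joint():
        # two congruent horizontal square facets, one above the other
        post = np.array([[-2, 1.0, -2], [2, 1.0, -2], [2, 1.0, 2], [-2, 1.0, 2.0]])
        pre = post - [0, 0.5, 0]
        fp = FacetPair(
            postzyg_poly=post, prezyg_poly=pre, normal=np.array([0, 1.0, 0]), side="left"
        )
        return make_locator_joint(
            [((0, 0, 0), (2, 0, 0), "disc")], cor=(0, 0, 0), facet_pairs=[fp]
        )

    def test_neutral_overlapping_facets(self):
        joint = self._facet_joint()
        assert not detect_disarticulation(joint, "dorsoflexion", 0.0)

    def test_fully_translated_facets(self):
        joint = self._facet_joint()
        for f in joint.facet_pairs:
            f.prezyg_poly = f.prezyg_poly + [10.0, 0, 0]
        assert detect_disarticulation(joint, "dorsoflexion", 0.0)

    def test_axial_flip_matches_polygon_sweep_oracle(self):
        from shapely.geometry import Polygon
        from osteorom._kernel import rotate_points

        joint = self._facet_joint()
        fp = joint.facet_pairs[0]
        # independent 2D sweep: rotate the prezyg polygon about the COR x-axis
        # and project onto the (x, z) plane (the facet plane)
        flip_oracle = None
        for k in range(1, 361):
            ang = k * 0.5
            pre = rotate_points(fp.prezyg_poly, [1.0, 0, 0], ang, [0, 0, 0])
            inter = Polygon(fp.postzyg_poly[:, [0, 2]]).intersection(
                Polygon(pre[:, [0, 2]])
            )
            if inter.area <= 1e-12:
                flip_oracle = ang
                break
        assert flip_oracle is not None
        engine_flip = None
        for k in range(1, 361):
            ang = k * 0.5
            if detect_disarticulation(joint, "left_axial", ang):
                engine_flip = ang
                break
        assert engine_flip == pytest.approx(flip_oracle, abs=0.5)

    def test_no_facets_reports_false(self):
        joint = make_locator_joint([((0, 0, 0), (2, 0, 0), "disc")], cor=(1, 0, 0))
        assert not detect_disarticulation(joint, "left_axial", 45.0)


@pytest.fixture(scope="module")
def tiny_column():
    return generate_column(SyntheticColumnSpec(n_vertebrae=2))


@pytest.fixture(scope="module")
def raw(tiny_column, tmp_path_factory):
    out = tmp_path_factory.mktemp("rom")
    table = run_experiment(tiny_column, out_dir=out)
    return table, out


class TestExperiment:
    def test_grid_cardinality(self):
        assert len(VariantGrid().variants()) == 27

    def test_record_count_single_joint(self, raw):
        table, _ = raw
        assert len(table) == 6 * 27  # 162

    def test_variant_columns_cover_grid(self, raw):
        table, _ = raw
        grid = VariantGrid()
        assert set(np.round(table["spacing_mult"], 6)) == set(grid.spacing_multipliers)
        assert set(np.round(table["threshold"], 6)) == set(grid.intersection_thresholds)
        assert set(np.round(table["strain_allow"], 6)) == set(
            np.round(grid.strain_allowances, 6)
        )

    def test_rom_is_step_multiple_within_cap(self, raw):
        table, _ = raw
        assert (table["rom_deg"] >= 0).all()
        assert (table["rom_deg"] <= 90.0).all()
        assert np.allclose(table["rom_deg"] % 0.5, 0.0)

    def test_rerun_is_byte_identical(self, tiny_column, raw, tmp_path):
        table, out = raw
        table2 = run_experiment(tiny_column, out_dir=tmp_path)
        pd.testing.assert_frame_equal(table.reset_index(drop=True), table2.reset_index(drop=True))
        f1 = sorted(out.glob("*.tsv"))[0]
        f2 = sorted(tmp_path.glob("*.tsv"))[0]
        assert f1.read_bytes() == f2.read_bytes()

    def test_per_joint_files_written(self, raw, tiny_column):
        _, out = raw
        assert len(list(out.glob("*.tsv"))) == tiny_column.n_joints


def test_unknown_direction_rejected(default_joint):
    with pytest.raises(ValueError, match="direction"):
        sweep_direction(default_joint, "sideways", BendingConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        BendingConfig(step=0.0)
    with pytest.raises(ValueError):
        BendingConfig(step=0.7, max_angle=90.0)  # not a multiple
    assert BendingConfig().n_steps == 180
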