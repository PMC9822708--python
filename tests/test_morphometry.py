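"""Mesh loading, sub-volume dissection, OP/HP classification, tract length."""

import numpy as np
import pytest

from tractacoustics.meshdata import MeshError, VolumeMesh, boundary_faces
from tractacoustics.morphometry import (
    DissectionConfig,
    Plane,
    dissect,
    load_mesh,
    morphometry,
    tract_length,
)
from tractacoustics.mshio import write_msh
from tractacoustics.synthetic import SceneSpec, export_stl, make_vt_mesh, voxel_mesh


@pytest.fixture(scope="module")
def small_cylinder():
    return make_vt_mesh(
        SceneSpec(
            shape="cylinder",
            axial_length=0.10,
            radius_profile=[(0.0, 0.01), (0.10, 0.01)],
            target_element_size=0.002,
        )
    )


class TestLoadMesh:
    def test_msh_round_trip(self, tmp_path, small_cylinder):
        path = tmp_path / "cyl.msh"
        write_msh(path, small_cylinder)
        back = load_mesh(path)
        assert len(back.nodes) == len(small_cylinder.nodes)
        assert back.A_g == pytest.approx(small_cylinder.A_g, rel=1e-9)
        assert back.A_l == pytest.approx(small_cylinder.A_l, rel=1e-9)
        assert back.volume == pytest.approx(small_cylinder.volume, rel=1e-9)

    def test_stl_without_patch_rule_errors(self, tmp_path, small_cylinder):
        path = tmp_path / "cyl.stl"
        export_stl(path, small_cylinder)
        with pytest.raises(MeshError, match="patches unresolved"):
            load_mesh(path)

    def test_stl_with_axial_rule(self, tmp_path, small_cylinder):
        path = tmp_path / "cyl.stl"
        export_stl(path, small_cylinder)
        mesh = load_mesh(path, patch_spec="axial", element_size=0.002)
        # voxel remeshing is a staircase approximation; areas agree coarsely
        assert mesh.A_g / mesh.A_l == pytest.approx(1.0, rel=0.15)
        assert mesh.volume == pytest.approx(small_cylinder.volume, rel=0.1)

    def test_cylinder_area_ratio(self, small_cylinder):
        assert small_cylinder.A_g / small_cylinder.A_l == pytest.approx(1.0, rel=0.02)


class TestDissect:
    def test_no_planes_puts_everything_in_one_label(self, small_cylinder):
        sub = dissect(small_cylinder, DissectionConfig(compartments=["OPf"]))
        assert sub.OPf == pytest.approx(small_cylinder.volume * 1e6, rel=1e-12)
        assert sub.OPr == sub.HPu == sub.HPl == sub.ET == sub.SP == sub.VV == 0.0

    def test_mid_plane_halves_cylinder(self, small_cylinder):
        sub = dissect(small_cylinder, DissectionConfig.axial_split(0.05))
        analytic_half = np.pi * 1.0**2 * 5.0  # cm^3
        assert sub.OPf == pytest.approx(analytic_half, rel=0.02)
        assert sub.HPl == pytest.approx(analytic_half, rel=0.02)

    def test_volume_conservation(self, small_cylinder):
        planes = [
            Plane("a", [0.03, 0, 0], [1, 0, 0]),
            Plane("b", [0.05, 0, 0], [1, 0, 0]),
            Plane("c", [0.08, 0, 0], [1, 0, 0]),
        ]
        cfg = DissectionConfig(planes=planes, compartments=["VV", "ET", "HPl", "OPf"])
        sub = dissect(small_cylinder, cfg)
        assert sub.V == pytest.approx(small_cylinder.volume * 1e6, rel=1e-9)

    def test_megaphone_classification(self):
        mega = make_vt_mesh(SceneSpec(shape="megaphone", target_element_size=0.004))
        inv = make_vt_mesh(
            SceneSpec(shape="inverted_megaphone", target_element_size=0.004)
        )
        cfg = DissectionConfig.axial_split(0.5 * 0.175)
        assert dissect(mega, cfg).OP / dissect(mega, cfg).HP > 1.0
        sub = dissect(inv, cfg)
        assert sub.OP / sub.HP < 1.0


class TestMorphometry:
    def test_equal_volumes_give_unit_ratio(self):
        from tractacoustics.morphometry import SubvolumeSet

        sub = SubvolumeSet(OPf=3.0, OPr=1.0, HPl=4.0)
        assert morphometry(sub, 10.0).op_hp_ratio == pytest.approx(1.0)

    def test_reported_megaphone_ratio_arithmetic(self):
        from tractacoustics.morphometry import SubvolumeSet

        sub = SubvolumeSet(OPf=7.6, HPl=1.0)
        assert morphometry(sub, 11.48).op_hp_ratio == pytest.approx(7.6)

    def test_all_mass_hypopharyngeal_gives_zero(self):
        from tractacoustics.morphometry import SubvolumeSet

        assert morphometry(SubvolumeSet(HPl=5.0), 10.0).op_hp_ratio == 0.0

    def test_zero_hp_undefined(self):
        from tractacoustics.morphometry import SubvolumeSet

        assert morphometry(SubvolumeSet(OPf=5.0), 10.0).op_hp_ratio is None


class TestTractLength:
    def test_straight_cylinder(self, cylinder_mesh):
        assert tract_length(cylinder_mesh) == pytest.approx(17.5, rel=0.02)

    def test_rotation_invariance(self, cylinder_mesh):
        # exactly orthogonal rational rotation matrix
        R = np.array(
            [[0.36, -0.48, 0.8], [0.8, 0.6, 0.0], [-0.48, 0.64, 0.6]]
        )
        rotated = VolumeMesh(
            nodes=cylinder_mesh.nodes @ R.T,
            tets=cylinder_mesh.tets.copy(),
            patches=cylinder_mesh.patches,
            r_l=cylinder_mesh.r_l,
        )
        L0 = tract_length(cylinder_mesh)
        L1 = tract_length(rotated)
        assert abs(L1 - L0) / L0 < 1e-6

    def test_bent_tube(self):
        # two 8 cm arms of radius 1 cm meeting at a right angle
        def inside(p):
            x, y, z = p[:, 0], p[:, 1], p[:, 2]
            arm1 = (x > 0) & (x < 0.08) & (y**2 + z**2 < 0.01**2)
            arm2 = (
                (x > 0.07) & (x < 0.09) & (y > 0) & (y < 0.08)
                & ((x - 0.08) ** 2 + z**2 < 0.01**2)
            )
            return arm1 | arm2

        nodes, tets = voxel_mesh(
            inside,
            (np.array([0, -0.012, -0.012]), np.array([0.09, 0.081, 0.012])),
            0.002,
        )
        bnd = boundary_faces(tets)
        cx, cy = nodes[bnd, 0], nodes[bnd, 1]
        ymax = nodes[:, 1].max()
        gl = (np.abs(cx) < 1e-9).all(axis=1)
        lp = (np.abs(cy - ymax) < 1e-9).all(axis=1)
        mesh = VolumeMesh(
            nodes=nodes,
            tets=tets,
            patches={"glottis": bnd[gl], "lips": bnd[lp], "wall": bnd[~(gl | lp)]},
            r_l=0.006,
        )
        mesh.validate()
        oracle = (0.08 + ymax) * 100  # sum of segment axes, cm
        assert tract_length(mesh) == pytest.approx(oracle, rel=0.05)


def test_reference_table_length_spread():
    from tractacoustics.data import reference_morphometry

    df = reference_morphometry()
    assert df["L_cm"].max() - df["L_cm"].min() >= 5.2
    # classification context: megaphone-type qualities exceed 1 for /a:/
    aa = df[df.vowel == "aa"]
    assert (aa[aa.quality.isin(["Belting", "Twang"])]["op_hp_ratio"] > 1).all()
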