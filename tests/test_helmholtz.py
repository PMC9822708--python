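"""FEM Helmholtz solver: oracles, limiting cases, physical invariants."""

import numpy as np
import pytest

from tractacoustics.helmholtz import (
    AcousticConfig,
    TransferFunction,
    elements_per_wavelength,
    find_resonances,
    radiation_impedance,
    solve_sweep,
    transfer_functions,
    vvtf,
    wall_admittance,
)
from tractacoustics.synthetic import SceneSpec, make_vt_mesh

C = 353.0
RHO = 1.13


def closed_open_oracle(L, r, c=C):
    """First resonance of a 1-D closed-open tube with 0.6 r end correction."""
    return c / (4.0 * (L + 0.6 * r))


class TestRadiationImpedance:
    def test_plane_wave_limit(self):
        z = radiation_impedance(2 * np.pi * 1e7, 0.01)
        assert z == pytest.approx(RHO * C, rel=1e-3)

    def test_mass_like_limit(self):
        omega = 2 * np.pi * 1.0
        z = radiation_impedance(omega, 0.01)
        assert z == pytest.approx(1j * omega * RHO * 0.01, rel=1e-3)
        assert abs(z) < 1e-3 * RHO * C

    def test_unit_kr(self):
        omega = C / 0.01  # kr = 1
        z = radiation_impedance(omega, 0.01)
        assert z == pytest.approx(RHO * C * (0.5 + 0.5j), rel=1e-12)

    def test_elements_per_wavelength_and_mu(self):
        assert int(elements_per_wavelength(0.0026, 10000.0, C)) == 13
        assert int(elements_per_wavelength(0.00143, 10000.0, C)) == 24
        assert wall_admittance(200.0 * RHO * C) == pytest.approx(0.005, abs=1e-15)


class TestCylinderOracles:
    def test_first_resonance_matches_transmission_line(self, rigid_cylinder_sweep):
        res = find_resonances(rigid_cylinder_sweep["v_gl"], 1.0)
        assert res.maxima, "no resonance found below 700 Hz"
        f_r1 = res.maxima[0][0]
        assert f_r1 == pytest.approx(closed_open_oracle(0.175, 0.0125), rel=0.03)

    def test_vvtf_low_frequency_continuity(self, rigid_cylinder_sweep):
        level0 = 20 * np.log10(abs(rigid_cylinder_sweep["v_gl"].values[0]))
        assert abs(level0) <= 0.5  # 0 dB at 10 Hz

    def test_transfer_functions_equal_pressures_for_unit_v0(
        self, rigid_cylinder_sweep
    ):
        sweep = rigid_cylinder_sweep["sweep"]
        h_gl = rigid_cylinder_sweep["h_gl"]
        assert np.allclose(h_gl.values, sweep.p_l)

    def test_grid_convergence_of_f_r1(self):
        f_r1 = []
        for h in (0.004, 0.002):
            mesh = make_vt_mesh(
                SceneSpec(shape="cylinder", target_element_size=h)
            )
            cfg = AcousticConfig(mu=0.0, f_grid=np.arange(400.0, 561.0, 10.0))
            sweep = solve_sweep(mesh, cfg)
            h_gl, _ = transfer_functions(sweep, cfg, mesh)
            v = vvtf(h_gl, mesh.A_g, mesh.A_l, sweep.Z_l)
            res = find_resonances(v, 0.1)
            f_r1.append(res.maxima[0][0])
        assert abs(f_r1[1] - f_r1[0]) / f_r1[1] < 0.01

    def test_damping_monotonicity(self, cylinder_mesh):
        peaks = []
        for mu in (0.005, 0.02, 0.08):
            cfg = AcousticConfig(mu=mu, f_grid=np.arange(400.0, 561.0, 10.0))
            sweep = solve_sweep(cylinder_mesh, cfg)
            h_gl, _ = transfer_functions(sweep, cfg, cylinder_mesh)
            v = vvtf(h_gl, cylinder_mesh.A_g, cylinder_mesh.A_l, sweep.Z_l)
            peaks.append(20 * np.log10(np.abs(v.values)).max())
            assert np.isfinite(peaks[-1])
        assert peaks[0] > peaks[1] > peaks[2]

    def test_geometric_similarity_scaling(self):
        """Scaling the mesh by s scales resonances by 1/s (within 1%)."""
        from tractacoustics.meshdata import VolumeMesh

        base = make_vt_mesh(
            SceneSpec(
                shape="cylinder",
                axial_length=0.06,
                radius_profile=[(0.0, 0.01), (0.06, 0.01)],
                target_element_size=0.003,
            )
        )
        s = 0.5
        scaled = VolumeMesh(
            nodes=base.nodes * s,
            tets=base.tets.copy(),
            patches=base.patches,
            r_l=base.r_l * s,
        )
        found = []
        for mesh, band in ((base, (1100, 1500)), (scaled, (2200, 3000))):
            cfg = AcousticConfig(
                mu=0.0, f_grid=np.arange(band[0], band[1] + 1.0, 20.0)
            )
            sweep = solve_sweep(mesh, cfg)
            h_gl, _ = transfer_functions(sweep, cfg, mesh)
            v = vvtf(h_gl, mesh.A_g, mesh.A_l, sweep.Z_l)
            res = find_resonances(v, 0.1)
            found.append(res.maxima[0][0])
        assert found[1] == pytest.approx(found[0] / s, rel=0.01)


class TestSideBranch:
    def test_antiresonance_at_quarter_wave(self, side_branch_result):
        minima = side_branch_result["resonances"].minima
        assert minima, "no antiresonance found in the sweep band"
        deepest = min(minima, key=lambda m: m[1])
        oracle = C / (4.0 * 0.022)
        assert deepest[0] == pytest.approx(oracle, rel=0.05)


class TestVVTFAlgebra:
    def test_identity_when_pressure_matches_impedance(self):
        f = np.arange(10.0, 101.0, 10.0)
        Z = radiation_impedance(2 * np.pi * f, 0.01)
        h = TransferFunction("H_gl", f, Z.copy())
        v = vvtf(h, 1e-4, 1e-4, Z)
        assert np.allclose(np.abs(v.values), 1.0)

    def test_halving_glottal_area_doubles_vvtf(self):
        f = np.arange(10.0, 101.0, 10.0)
        Z = radiation_impedance(2 * np.pi * f, 0.01)
        h = TransferFunction("H_gl", f, np.full(len(f), 2.0 + 1.0j))
        v1 = vvtf(h, 1e-4, 2e-4, Z)
        v2 = vvtf(h, 0.5e-4, 2e-4, Z)
        assert np.allclose(np.abs(v2.values), 2.0 * np.abs(v1.values))

    def test_zero_impedance_rejected(self):
        f = np.arange(10.0, 41.0, 10.0)
        h = TransferFunction("H_gl", f, np.ones(len(f), complex))
        with pytest.raises(ValueError):
            vvtf(h, 1e-4, 1e-4, np.array([1.0, 0.0, 1.0, 1.0], complex))


class TestFindResonances:
    def test_single_lorentzian_peak(self):
        f = np.arange(10.0, 5001.0, 10.0)
        mag = 1.0 / np.sqrt(1.0 + ((f - 1000.0) / 80.0) ** 2)
        res = find_resonances(TransferFunction("V_gl", f, mag.astype(complex)), 1.0)
        assert len(res.maxima) == 1
        assert res.maxima[0][0] == pytest.approx(1000.0, abs=10.0)

    def test_monotone_curve_has_no_extrema(self):
        f = np.arange(10.0, 1001.0, 10.0)
        res = find_resonances(
            TransferFunction("V_gl", f, np.exp(-f / 500.0).astype(complex)), 1.0
        )
        assert res.maxima == [] and res.minima == []

    def test_nonuniform_grid_rejected(self):
        f = np.array([10.0, 20.0, 40.0, 80.0])
        with pytest.raises(ValueError):
            find_resonances(TransferFunction("V_gl", f, np.ones(4, complex)), 1.0)
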