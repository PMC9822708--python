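"""Shared fixtures: meshes and FEM sweeps reused across test modules.

The FEM sweeps are the expensive part of the suite, so they are solved once
per session on deliberately small scenes (short tubes, narrow frequency
bands) and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from tractacoustics.helmholtz import (
    AcousticConfig,
    solve_sweep,
    transfer_functions,
    vvtf,
)
from tractacoustics.synthetic import SceneSpec, make_vt_mesh

CYL_L = 0.175
CYL_R = 0.0125
BRANCH_LB = 0.022


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Closed-open reference cylinder: L = 17.5 cm, r = 1.25 cm, 3 mm mesh."""
    return make_vt_mesh(
        SceneSpec(shape="cylinder", axial_length=CYL_L, target_element_size=0.003)
    )


@pytest.fixture(scope="session")
def rigid_cylinder_sweep(cylinder_mesh):
    """Rigid-walled (mu = 0) sweep over 10-700 Hz in 10 Hz steps."""
    cfg = AcousticConfig(mu=0.0, f_grid=np.arange(10.0, 701.0, 10.0))
    sweep = solve_sweep(cylinder_mesh, cfg)
    h_gl, h_gg = transfer_functions(sweep, cfg, cylinder_mesh)
    v_gl = vvtf(h_gl, cylinder_mesh.A_g, cylinder_mesh.A_l, sweep.Z_l)
    return {"cfg": cfg, "sweep": sweep, "h_gl": h_gl, "h_gg": h_gg, "v_gl": v_gl}


@pytest.fixture(scope="session")
def small_tract_tfs():
    """Short cylinder swept over the full 10 kHz band (50 Hz steps).

    Small enough to solve in seconds; used for filter fitting and
    back-filtering round trips where the geometry itself is irrelevant.
    """
    mesh = make_vt_mesh(
        SceneSpec(
            shape="cylinder",
            axial_length=0.06,
            radius_profile=[(0.0, 0.01), (0.06, 0.01)],
            target_element_size=0.003,
        )
    )
    cfg = AcousticConfig(f_grid=np.arange(10.0, 10001.0, 50.0))
    sweep = solve_sweep(mesh, cfg)
    h_gl, h_gg = transfer_functions(sweep, cfg, mesh)
    return {"mesh": mesh, "cfg": cfg, "sweep": sweep, "h_gl": h_gl, "h_gg": h_gg}


@pytest.fixture(scope="session")
def side_branch_result():
    """Tube with a closed side branch of 2.2 cm acoustic length.

    Swept only around the expected quarter-wave antiresonance
    (c / (4 l_b) ~ 4.0 kHz) to keep the voxel-mesh solve affordable.
    """
    from tractacoustics.helmholtz import find_resonances

    spec = SceneSpec(
        shape="cylinder_with_side_branch",
        axial_length=0.07,
        radius_profile=[(0.0, 0.01), (0.07, 0.01)],
        branch=(0.035, BRANCH_LB, 0.004),
        target_element_size=0.00135,
    )
    mesh = make_vt_mesh(spec)
    cfg = AcousticConfig(mu=0.005, f_grid=np.arange(3500.0, 4501.0, 25.0))
    sweep = solve_sweep(mesh, cfg)
    h_gl, _ = transfer_functions(sweep, cfg, mesh)
    v_gl = vvtf(h_gl, mesh.A_g, mesh.A_l, sweep.Z_l)
    resonances = find_resonances(v_gl, 1.0)
    return {"mesh": mesh, "v_gl": v_gl, "resonances": resonances, "spec": spec}
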