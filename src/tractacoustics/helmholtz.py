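"""Finite-element Helmholtz acoustics of the vocal-tract cavity.

Solves, per excitation frequency, the interior Helmholtz problem

    nabla^2 p + kappa^2 p = 0,   kappa = omega / c,

for the complex pressure ``p`` on a tagged tetrahedral mesh with

* a Neumann velocity source on the glottal patch:
  ``grad p . n = -j omega rho0 V0``,
* a locally reacting wall impedance ``Z_w = rho0 c / mu`` on the wall patch
  (Robin condition ``grad p . n = -j kappa (rho0 c / Z_w) p``),
* a spherical-wave radiation impedance on the lip patch:
  ``Z_l(omega) = rho0 c (j kappa r_l) / (1 + j kappa r_l)``.

Linear (P1) tetrahedral elements, one sparse complex direct solve per
frequency.  Outputs are the pressure transfer functions ``H_gl`` (glottis
velocity to lip pressure) and ``H_gg`` (to glottal pressure), the
dimensionless volume-velocity transfer function (VVTF)

    V_gl(omega) = p_l A_l / (Z_l V0 A_g),

which tends to 0 dB at low frequency for a simply connected cavity, and the
resonance (maxima ``f_Rn``) and antiresonance (minima ``L_Rn``) sets of a
transfer-function level curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.signal import find_peaks

from .meshdata import VolumeMesh, tet_volumes, triangle_areas

__all__ = [
    "AcousticConfig",
    "FieldSweep",
    "TransferFunction",
    "ResonanceSet",
    "elements_per_wavelength",
    "wall_admittance",
    "radiation_impedance",
    "solve_sweep",
    "transfer_functions",
    "vvtf",
    "find_resonances",
]


def _default_grid() -> np.ndarray:
    return np.arange(10.0, 10000.0 + 1e-9, 10.0)


@dataclass
class AcousticConfig:
    """Physical constants and sweep settings.

    ``c`` and ``rho0`` default to moist air at body temperature (37 C).
    ``mu`` is the dimensionless wall admittance coefficient, equivalent to a
    real wall impedance ``Z_w = rho0 c / mu`` (the default 0.005 corresponds
    to ``Z_w = 200 rho0 c``).  The frequency grid excludes 0 Hz, where the
    source term vanishes and the rigid-wall operator is singular.
    """

    c: float = 353.0  # m/s
    rho0: float = 1.13  # kg/m^3
    mu: float = 0.005
    V0: float = 1.0  # m/s
    f_grid: np.ndarray = field(default_factory=_default_grid)
    prominence_dB: float = 1.0

    def __post_init__(self):
        self.f_grid = np.asarray(self.f_grid, dtype=float)
        if self.c <= 0 or self.rho0 <= 0:
            raise ValueError("c and rho0 must be positive")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must lie in [0, 1)")
        if len(self.f_grid) and (
            self.f_grid.min() <= 0 or (np.diff(self.f_grid) <= 0).any()
        ):
            raise ValueError("f_grid must be strictly increasing and positive")

    @classmethod
    def desk(cls, **kw) -> "AcousticConfig":
        """Reduced sweep for interactive use and tests: 10 Hz..5 kHz, 25 Hz."""
        kw.setdefault("f_grid", np.arange(10.0, 5000.0 + 1e-9, 25.0))
        return cls(**kw)

    @classmethod
    def paper_preset(cls, **kw) -> "AcousticConfig":
        """Full-resolution sweep: 10 Hz..10 kHz in 10 Hz steps."""
        kw.setdefault("f_grid", _default_grid())
        return cls(**kw)


def wall_admittance(Z_w: float, cfg: AcousticConfig | None = None) -> float:
    """Dimensionless admittance coefficient ``mu = rho0 c / Z_w``."""
    cfg = cfg or AcousticConfig()
    return cfg.rho0 * cfg.c / Z_w


def elements_per_wavelength(
    element_size: float, f: float, c: float = 353.0
) -> float:
    """Linear elements per wavelength ``(c/f) / h`` at frequency ``f``."""
    return (c / f) / element_size


def radiation_impedance(
    omega: float | np.ndarray, r_l: float, cfg: AcousticConfig | None = None
) -> complex | np.ndarray:
    """Spherical-wave radiation impedance of the lip opening.

    ``Z_l = rho0 c (j k r_l) / (1 + j k r_l)``: mass-like (``j omega rho0
    r_l``) for ``k r_l << 1`` and approaching the plane-wave impedance
    ``rho0 c`` for ``k r_l >> 1``.
    """
    cfg = cfg or AcousticConfig()
    if r_l <= 0:
        raise ValueError("r_l must be positive")
    kr = np.asarray(omega) / cfg.c * r_l
    z = cfg.rho0 * cfg.c * (1j * kr) / (1.0 + 1j * kr)
    return complex(z) if np.isscalar(omega) else z


@dataclass
class FieldSweep:
    """Per-frequency field samples at the patch-center nodes."""

    frequencies: np.ndarray
    p_l: np.ndarray  # complex Pa at the central lip node
    p_g: np.ndarray  # complex Pa at the central glottis node
    Z_l: np.ndarray  # radiation impedance used, Pa s/m
    failed: list[float] = field(default_factory=list)


@dataclass
class TransferFunction:
    """Complex frequency response with kind-specific units.

    Kinds: ``H_gl``/``H_gg`` in Pa s/m, ``V_gl`` dimensionless.
    """

    kind: str
    frequencies: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def level_dB(self) -> np.ndarray:
        return 20.0 * np.log10(np.abs(self.values))


@dataclass
class ResonanceSet:
    """Transfer-function maxima (f_Rn) and minima (L_Rn), ascending in Hz."""

    maxima: list[tuple[float, float]]  # (frequency Hz, level dB)
    minima: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _volume_matrices(mesh: VolumeMesh) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    nodes, tets = mesh.nodes, mesh.tets
    vol = tet_volumes(nodes, tets)
    e = nodes[tets[:, 1:]] - nodes[tets[:, :1]]  # (M, 3, 3) edge matrix rows
    inv = np.linalg.inv(e)  # columns are gradients of lambda_1..3
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    ke = np.einsum("mik,mjk,m->mij", grads, grads, vol)
    me = (np.ones((4, 4)) + np.eye(4))[None, :, :] * (vol / 20.0)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    n = len(nodes)
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K, M


def _surface_matrix(mesh: VolumeMesh, patch: str) -> sp.csr_matrix:
    tris = mesh.patches[patch]
    area = triangle_areas(mesh.nodes, tris)
    be = (np.ones((3, 3)) + np.eye(3))[None, :, :] * (area / 12.0)[:, None, None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    n = len(mesh.nodes)
    return sp.coo_matrix((be.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _load_vector(mesh: VolumeMesh) -> np.ndarray:
    tris = mesh.patches["glottis"]
    area = triangle_areas(mesh.nodes, tris)
    g = np.zeros(len(mesh.nodes))
    np.add.at(g, tris.ravel(), np.repeat(area / 3.0, 3))
    return g


def solve_sweep(
    mesh: VolumeMesh,
    cfg: AcousticConfig | None = None,
    max_fail_fraction: float = 0.01,
) -> FieldSweep:
    """Frequency sweep of the FEM Helmholtz problem on ``mesh``.

    Pressure is sampled at the node nearest each patch's area-weighted
    centroid.  Warns when the mesh resolves fewer than 10 linear elements
    per wavelength at the top of the grid; aborts if more than
    ``max_fail_fraction`` of the frequencies fail to solve.
    """
    cfg = cfg or AcousticConfig()
    epw = elements_per_wavelength(
        mesh.mean_edge_length(), cfg.f_grid.max(), cfg.c
    )
    if epw < 10.0:
        warnings.warn(
            f"mesh resolves only {epw:.1f} elements per wavelength at "
            f"{cfg.f_grid.max():.0f} Hz (>= 10 recommended)",
            stacklevel=2,
        )
    K, M = _volume_matrices(mesh)
    B_w = _surface_matrix(mesh, "wall")
    B_l = _surface_matrix(mesh, "lips")
    g = _load_vector(mesh)
    i_l = mesh.patch_center_node("lips")
    i_g = mesh.patch_center_node("glottis")

    p_l = np.empty(len(cfg.f_grid), dtype=complex)
    p_g = np.empty(len(cfg.f_grid), dtype=complex)
    Z_ls = np.empty(len(cfg.f_grid), dtype=complex)
    failed: list[float] = []
    for i, f in enumerate(cfg.f_grid):
        omega = 2.0 * np.pi * f
        kappa = omega / cfg.c
        Z_l = radiation_impedance(omega, mesh.r_l, cfg)
        A = (
            K
            - kappa**2 * M
            + 1j * kappa * (cfg.mu * B_w + (cfg.rho0 * cfg.c / Z_l) * B_l)
        ).tocsc()
        b = -1j * omega * cfg.rho0 * cfg.V0 * g
        try:
            p = spla.splu(A.astype(complex)).solve(b.astype(complex))
            if not np.isfinite(p[[i_l, i_g]]).all():
                raise RuntimeError("non-finite solution")
        except Exception:
            failed.append(float(f))
            p_l[i] = p_g[i] = np.nan
            Z_ls[i] = Z_l
            continue
        p_l[i], p_g[i] = p[i_l], p[i_g]
        Z_ls[i] = Z_l
    if len(failed) > max_fail_fraction * len(cfg.f_grid):
        raise RuntimeError(
            f"sweep aborted: {len(failed)} of {len(cfg.f_grid)} frequencies failed"
        )
    return FieldSweep(
        frequencies=cfg.f_grid.copy(), p_l=p_l, p_g=p_g, Z_l=Z_ls, failed=failed
    )


def transfer_functions(
    sweep: FieldSweep, cfg: AcousticConfig | None = None, mesh: VolumeMesh | None = None
) -> tuple[TransferFunction, TransferFunction]:
    """``H_gl = p_l / V0`` and ``H_gg = p_g / V0`` from a completed sweep."""
    cfg = cfg or AcousticConfig()
    meta = {"V0": cfg.V0}
    if mesh is not None:
        meta.update(A_g=mesh.A_g, A_l=mesh.A_l, r_l=mesh.r_l)
    h_gl = TransferFunction(
        "H_gl", sweep.frequencies.copy(), sweep.p_l / cfg.V0, dict(meta)
    )
    h_gg = TransferFunction(
        "H_gg", sweep.frequencies.copy(), sweep.p_g / cfg.V0, dict(meta)
    )
    return h_gl, h_gg


def vvtf(
    h_gl: TransferFunction,
    A_g: float,
    A_l: float,
    Z_l: np.ndarray,
    V0: float = 1.0,
) -> TransferFunction:
    """Volume-velocity transfer function ``V_gl = p_l A_l / (Z_l V0 A_g)``.

    ``h_gl.values`` already carries ``p_l / V0`` so only the remaining
    normalization is applied here.  Dimensionless; 0 dB means the lip volume
    velocity equals the glottal volume velocity.
    """
    Z_l = np.asarray(Z_l)
    if (Z_l == 0).any():
        raise ValueError("Z_l must be nonzero on the whole grid")
    vals = h_gl.values * A_l / (Z_l * A_g)
    meta = dict(h_gl.metadata)
    meta.update(A_g=A_g, A_l=A_l, V0=V0)
    return TransferFunction("V_gl", h_gl.frequencies.copy(), vals, meta)


def find_resonances(
    tf: TransferFunction, prominence_dB: float = 1.0
) -> ResonanceSet:
    """Maxima/minima of the dB level curve with parabolic refinement.

    The frequency grid limits raw precision (e.g. 10 or 25 Hz steps), so
    each peak is refined with a three-point parabola through the level
    values around the discrete extremum.
    """
    f = np.asarray(tf.frequencies, dtype=float)
    if len(f) > 1 and not np.allclose(np.diff(f), f[1] - f[0]):
        raise ValueError("find_resonances requires a uniform frequency grid")
    level = 20.0 * np.log10(np.abs(tf.values))

    def refine(idx: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
        out = []
        df = f[1] - f[0] if len(f) > 1 else 0.0
        for i in idx:
            if 0 < i < len(f) - 1:
                denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
                out.append((f[i] + delta * df, y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta))
            else:
                out.append((f[i], y[i]))
        return out

    imax, _ = find_peaks(level, prominence=prominence_dB)
    imin, _ = find_peaks(-level, prominence=prominence_dB)
    maxima = refine(imax, level)
    minima = [(fr, -lv) for fr, lv in refine(imin, -level)]
    return ResonanceSet(maxima=maxima, minima=minima)


def tf_to_csv(path, *tfs: TransferFunction) -> None:
    """Write transfer functions as CSV columns (f_Hz, Re/Im per kind)."""
    import pandas as pd

    data = {"f_Hz": tfs[0].frequencies}
    for tf in tfs:
        data[f"Re_{tf.kind}"] = tf.values.real
        data[f"Im_{tf.kind}"] = tf.values.imag
    pd.DataFrame(data).to_csv(path, index=False)


def tf_from_csv(path, kind: str, metadata: dict | None = None) -> TransferFunction:
    import pandas as pd

    df = pd.read_csv(path)
    values = df[f"Re_{kind}"].to_numpy() + 1j * df[f"Im_{kind}"].to_numpy()
    return TransferFunction(kind, df["f_Hz"].to_numpy(), values, metadata or {})
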