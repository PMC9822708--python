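"""Synthetic test scenes: parametric cavities and source/EGG signals.

This module generates every input the analysis pipeline needs, with known
ground truth:

* axisymmetric tube/horn cavities (and a tube with a closed side branch)
  meshed into tagged tetrahedra, whose resonances follow 1-D duct acoustics;
* glottal-flow pulse trains with a prescribed harmonic spectral slope;
* electroglottography (EGG) waveforms with a prescribed contact quotient;
* forward-rendered "microphone" audio (convolution with an impulse response).

Shapes mimic the three vocal-tract configuration classes: ``megaphone``
(narrow pharynx, wide mouth), ``inverted_megaphone`` (wide pharynx, moderate
mouth) and neutral ``cylinder``; ``cylinder_with_side_branch`` adds a closed
lateral cavity (as the piriform sinus does) that introduces an antiresonance
near its quarter-wave frequency.

Geometry conventions: glottis plane at axial coordinate x = 0, lips at
x = +L, SI units (m) internally.  The lip patch is a flat disc; radiation is
represented downstream by a spherical-wave impedance with equivalent-sphere
radius ``r_l``, which defaults to 0.6 times the lip aperture radius so that
the low-frequency radiation mass matches the classic unflanged open-end
correction (0.6 a).  For the side branch, the ``branch length`` parameter is
the branch's acoustic quarter-wave length: the drilled geometric depth is
shortened by the flanged-opening end correction ``8/(3 pi) * r_b`` so the
prescribed antiresonance ``c / (4 l_b)`` is realized by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .meshdata import MeshError, VolumeMesh, boundary_faces, fix_orientation

__all__ = [
    "SceneSpec",
    "AudioSignal",
    "EGGSignal",
    "make_vt_mesh",
    "make_glottal_flow",
    "make_egg",
    "render_microphone",
    "pitch_frequency",
    "tube_mesh",
    "voxel_mesh",
    "write_wav",
    "read_wav",
]

BRANCH_END_CORRECTION = 8.0 / (3.0 * np.pi)  # flanged circular opening, x r_b
LIP_SPHERE_FACTOR = 0.6  # unflanged open-end correction, x aperture radius


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AudioSignal:
    """Sampled signal with calibration to physical units.

    ``calibration`` converts dimensionless sample units to Pa (for sound
    pressure) or m/s (for particle-velocity series); ``f_o`` is the task's
    fundamental frequency.
    """

    samples: np.ndarray
    fs: float
    calibration: float = 1.0
    f_o: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.samples).all():
            raise ValueError("non-finite samples")
        if self.fs <= 0 or self.calibration <= 0:
            raise ValueError("fs and calibration must be positive")

    @property
    def pascals(self) -> np.ndarray:
        return self.samples * self.calibration


@dataclass
class EGGSignal:
    """Relative vocal-fold contact area vs. time (dimensionless, 0..1)."""

    samples: np.ndarray
    fs: float
    f_o: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.samples).all():
            raise ValueError("non-finite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


_SHAPES = ("cylinder", "megaphone", "inverted_megaphone", "cylinder_with_side_branch")


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (geometry + source + EGG)."""

    shape: str = "cylinder"
    axial_length: float = 0.175
    radius_profile: list[tuple[float, float]] | None = None
    branch: tuple[float, float, float] | None = None  # (position, length, radius) m
    target_element_size: float = 0.003
    r_l: float | None = None  # equivalent radiating-sphere radius, m
    f_o: float = 208.0
    duration: float = 1.0
    fs: float = 20000.0
    source_slope: float = -12.0  # dB/octave
    contact_quotient: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.axial_length <= 0:
            raise ValueError("axial_length must be positive")
        if not 0.0 < self.contact_quotient < 1.0:
            raise ValueError("contact_quotient must lie in (0, 1)")
        if self.fs < 2.0 * 10000.0:
            raise ValueError("fs must be at least 20 kHz (2 x 10 kHz band)")
        if self.radius_profile is None:
            self.radius_profile = default_radius_profile(self.shape, self.axial_length)
        if any(r <= 0 for _, r in self.radius_profile):
            raise ValueError("radii must be positive")
        if self.shape == "cylinder_with_side_branch":
            if self.branch is None:
                self.branch = (0.5 * self.axial_length, 0.022, 0.004)
            pos, lb, rb = self.branch
            if not 0.0 < pos < self.axial_length:
                raise ValueError("branch must attach strictly between glottis and lips")
            if lb <= 0 or rb <= 0:
                raise ValueError("branch length and radius must be positive")

    def radius_at(self, x) -> np.ndarray:
        xs, rs = zip(*self.radius_profile)
        return np.interp(x, xs, rs)


def default_radius_profile(shape: str, L: float) -> list[tuple[float, float]]:
    if shape in ("cylinder", "cylinder_with_side_branch"):
        return [(0.0, 0.0125), (L, 0.0125)]
    if shape == "megaphone":  # narrow pharynx opening into a wide mouth
        return [(0.0, 0.008), (0.55 * L, 0.009), (L, 0.021)]
    # inverted megaphone: wide pharynx, moderate mouth opening
    return [(0.0, 0.013), (0.45 * L, 0.019), (L, 0.009)]


def pitch_frequency(note: str, a4: float = 440.0) -> float:
    """Equal-tempered frequency of a pitch like ``"Ab4"`` or ``"A4"``.

    Accidentals: ``b`` flat, ``#`` sharp.  A4 defaults to 440 Hz.
    """
    base = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
    letter = note[0].upper()
    rest = note[1:]
    semis = base[letter]
    while rest and rest[0] in "b#":
        semis += 1 if rest[0] == "#" else -1
        rest = rest[1:]
    octave = int(rest)
    midi = 12 * (octave + 1) + semis
    return a4 * 2.0 ** ((midi - 69) / 12.0)


# ---------------------------------------------------------------------------
# tetrahedral meshing primitives
# ---------------------------------------------------------------------------

# orientation-preserving prism symmetries that bring vertex i to slot 0
_PRISM_ROT = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (bottom v0 v1 v2, top v3 v4 v5) into 3 tets each.

    Diagonals on the quadrilateral faces are chosen by global vertex index
    (smallest-index rule), which makes the split conforming across prisms
    that share a face.
    """
    prisms = np.asarray(prisms)
    rot = _PRISM_ROT[np.argmin(prisms, axis=1)]
    p = np.take_along_axis(prisms, rot, axis=1)
    cond = np.minimum(p[:, 1], p[:, 5]) < np.minimum(p[:, 2], p[:, 4])
    tets = np.empty((len(p), 3, 4), dtype=prisms.dtype)
    a = p[cond]
    tets[cond] = np.stack(
        [a[:, [0, 1, 2, 5]], a[:, [0, 1, 5, 4]], a[:, [0, 4, 5, 3]]], axis=1
    )
    b = p[~cond]
    tets[~cond] = np.stack(
        [b[:, [0, 1, 2, 4]], b[:, [0, 4, 2, 5]], b[:, [0, 4, 5, 3]]], axis=1
    )
    return tets.reshape(-1, 4)


def _disk_local_triangles(n_r: int, n_theta: int) -> np.ndarray:
    """Triangulation of the structured disk layout (center + n_r rings)."""

    def ring(k: int, t: int) -> int:
        return 1 + (k - 1) * n_theta + t % n_theta

    tris = []
    for t in range(n_theta):
        tris.append([0, ring(1, t), ring(1, t + 1)])
    for k in range(1, n_r):
        for t in range(n_theta):
            a, b = ring(k, t), ring(k, t + 1)
            c, d = ring(k + 1, t), ring(k + 1, t + 1)
            tris.append([a, c, b])
            tris.append([b, c, d])
    return np.asarray(tris, dtype=int)


def tube_mesh(
    x_positions: np.ndarray,
    radii: np.ndarray,
    n_r: int,
    n_theta: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Structured tet mesh of an axisymmetric tube/horn along +x.

    Returns ``(nodes, tets)``.  Cross sections are regular polygon disks
    (center node + ``n_r`` rings of ``n_theta`` nodes); consecutive sections
    are joined by prisms split into tets with the smallest-index rule.
    """
    x_positions = np.asarray(x_positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_sec = 1 + n_r * n_theta
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    unit = np.concatenate(
        [
            np.zeros((1, 2)),
            np.concatenate(
                [
                    np.stack([np.cos(theta), np.sin(theta)], axis=1) * (k / n_r)
                    for k in range(1, n_r + 1)
                ]
            ),
        ]
    )
    nodes = np.empty((len(x_positions) * n_sec, 3))
    for i, (x, r) in enumerate(zip(x_positions, radii)):
        nodes[i * n_sec : (i + 1) * n_sec, 0] = x
        nodes[i * n_sec : (i + 1) * n_sec, 1:] = unit * r
    tris = _disk_local_triangles(n_r, n_theta)
    prisms = []
    for i in range(len(x_positions) - 1):
        lo = tris + i * n_sec
        hi = tris + (i + 1) * n_sec
        prisms.append(np.concatenate([lo, hi], axis=1))
    tets = split_prisms(np.concatenate(prisms))
    tets = fix_orientation(nodes, tets)
    return nodes, tets


_KUHN = np.array(
    [  # six tets of the unit cube, conforming across neighbouring cells
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)],
    ]
)


def voxel_mesh(
    inside,
    bounds: tuple[np.ndarray, np.ndarray],
    h: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Tet mesh of an implicit solid: cells whose center satisfies ``inside``.

    ``inside(points)`` maps (N, 3) coordinates to booleans.  The grid spacing
    is adjusted per axis so the bounding box is covered by whole cells.
    Returns ``(nodes, tets)``; the boundary is a voxel staircase.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    h = np.broadcast_to(np.asarray(h, dtype=float), (3,))
    n = np.maximum(1, np.round((hi - lo) / h).astype(int))
    step = (hi - lo) / n
    # cell centers
    axes = [lo[d] + step[d] * (np.arange(n[d]) + 0.5) for d in range(3)]
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    keep = np.asarray(inside(centers), dtype=bool)
    if not keep.any():
        raise MeshError("voxel mesh: no cells inside the solid")
    cells = np.stack(np.unravel_index(np.nonzero(keep)[0], n), axis=1)
    # global vertex ids on the (n+1)^3 lattice
    mult = np.array([(n[1] + 1) * (n[2] + 1), n[2] + 1, 1])
    corners = cells[:, None, None, :] + _KUHN[None, :, :, :]
    vid = (corners * mult).sum(axis=-1)  # (ncell, 6, 4)
    tets_raw = vid.reshape(-1, 4)
    used, tets = np.unique(tets_raw, return_inverse=True)
    tets = tets.reshape(-1, 4)
    ijk = np.stack(np.unravel_index(used, n + 1), axis=1)
    nodes = lo + ijk * step
    tets = fix_orientation(nodes, tets.astype(int))
    return nodes, tets


def _classify_patches(
    nodes: np.ndarray, tets: np.ndarray, L: float
) -> dict[str, np.ndarray]:
    """Tag boundary faces: glottis at x=0, lips at x=L, wall elsewhere."""
    bnd = boundary_faces(tets)
    cx = nodes[bnd, 0]
    tol = 1e-9 + 1e-6 * L
    glottis = (np.abs(cx) < tol).all(axis=1)
    lips = (np.abs(cx - L) < tol).all(axis=1)
    return {
        "glottis": bnd[glottis],
        "lips": bnd[lips],
        "wall": bnd[~(glottis | lips)],
    }


def make_vt_mesh(spec: SceneSpec) -> VolumeMesh:
    """Build the tagged cavity mesh for a scene.

    Tube/horn shapes use the structured extruded mesher; the side-branch
    shape uses the voxel mesher (the branch junction is not extrudable).
    Raises :class:`MeshError` for unmeshable input (e.g. element size larger
    than the narrowest radius) and validates the result before returning.
    """
    L = spec.axial_length
    h = spec.target_element_size
    radii = np.array([r for _, r in spec.radius_profile])
    if h > radii.min():
        raise MeshError(
            f"target element size {h} m exceeds the minimum profile radius "
            f"{radii.min()} m; the cross section would be unresolved"
        )
    if spec.shape == "cylinder_with_side_branch":
        nodes, tets = _branch_voxel_mesh(spec)
    else:
        n_x = max(2, int(round(L / h)))
        x = np.linspace(0.0, L, n_x + 1)
        r = spec.radius_at(x)
        r_max = float(radii.max())
        n_r = max(2, int(round(r_max / h)))
        n_theta = max(16, int(np.ceil(2.0 * np.pi * r_max / h)))
        nodes, tets = tube_mesh(x, r, n_r, n_theta)
    patches = _classify_patches(nodes, tets, L)
    aperture = float(np.sqrt(
        np.maximum(nodes[np.unique(patches["lips"])][:, 1:] ** 2, 0).sum(axis=1).max()
    )) if len(patches["lips"]) else float(spec.radius_at(L))
    r_l = spec.r_l if spec.r_l is not None else LIP_SPHERE_FACTOR * aperture
    mesh = VolumeMesh(
        nodes=nodes, tets=tets, patches=patches, r_l=r_l, name=spec.shape
    )
    mesh.validate()
    return mesh


def _branch_voxel_mesh(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    L = spec.axial_length
    pos, lb, rb = spec.branch
    h = spec.target_element_size
    if h > rb:
        raise MeshError(
            f"target element size {h} m exceeds the branch radius {rb} m"
        )
    wall_y = float(spec.radius_at(pos))
    depth = lb - BRANCH_END_CORRECTION * rb  # acoustic length -> geometric depth
    if depth <= 0:
        raise MeshError("branch length shorter than its own end correction")
    y_tip = wall_y + depth
    r_max = float(max(r for _, r in spec.radius_profile))

    def inside(p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        in_main = (
            (x > 0.0) & (x < L) & (y**2 + z**2 < spec.radius_at(x) ** 2)
        )
        in_branch = (
            ((x - pos) ** 2 + z**2 < rb**2) & (y >= 0.0) & (y < y_tip)
        )
        return in_main | in_branch

    lo = np.array([0.0, -r_max, -r_max])
    hi = np.array([L, y_tip, r_max])
    return voxel_mesh(inside, (lo, hi), h)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


def make_glottal_flow(
    f_o: float,
    duration: float,
    fs: float,
    source_slope: float,
    seed: int,
    f_max: float = 10000.0,
) -> AudioSignal:
    """Periodic glottal-flow pulse train with a prescribed spectral slope.

    A sum of harmonics of ``f_o`` up to ``f_max`` whose magnitudes fall at
    ``source_slope`` dB/octave, with seeded random phases.  Only periodicity
    and the harmonic slope matter downstream, so no physiological pulse shape
    is imposed.
    """
    if source_slope > 0:
        raise ValueError("source_slope must be <= 0 dB/octave")
    if f_o >= fs / 2:
        raise ValueError("f_o must be below the Nyquist frequency")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    k_max = int(np.floor(min(f_max, 0.999 * fs / 2) / f_o))
    k = np.arange(1, k_max + 1)
    # magnitude law: 20 log10 a_k = slope * log2 k
    a = k ** (source_slope / (20.0 * np.log10(2.0)))
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k_max)
    x = (a[:, None] * np.sin(2.0 * np.pi * np.outer(k * f_o, t) + phases[:, None])).sum(
        axis=0
    )
    x *= 0.5 / np.abs(x).max()
    return AudioSignal(samples=x, fs=fs, calibration=1.0, f_o=f_o)


def make_egg(
    f_o: float,
    duration: float,
    fs: float,
    contact_quotient: float,
    seed: int,
    noise_level: float = 0.003,
) -> EGGSignal:
    """EGG waveform with a prescribed contact quotient.

    Each cycle is a raised-cosine contacting rise, a full-contact plateau, a
    raised-cosine de-contacting fall and an open plateau (amplitude 0..1).
    The fraction of the cycle above the 50% level equals ``contact_quotient``
    by construction; higher contact quotients also get steeper contacting
    phases, mirroring the physiological covariation of firm glottal closure
    with fast vocal-fold collision.
    """
    cq = contact_quotient
    if not 0.0 < cq < 1.0:
        raise ValueError("contact_quotient must lie in (0, 1)")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = (t * f_o) % 1.0
    # phase fractions of rise/fall; faster contacting for higher cq
    pr = min(0.25 * (1.0 - cq), cq)
    pf = pr
    ph = cq - 0.5 * (pr + pf)  # high-plateau fraction; >= 0 by choice of pr
    x = np.zeros(n)
    rise = phase < pr
    x[rise] = 0.5 * (1.0 - np.cos(np.pi * phase[rise] / pr))
    high = (phase >= pr) & (phase < pr + ph)
    x[high] = 1.0
    fall = (phase >= pr + ph) & (phase < pr + ph + pf)
    x[fall] = 0.5 * (1.0 + np.cos(np.pi * (phase[fall] - pr - ph) / pf))
    rng = np.random.default_rng(seed)
    if noise_level > 0:
        x = x + rng.normal(0.0, noise_level, size=n)
    return EGGSignal(samples=x, fs=fs, f_o=f_o)


def render_microphone(
    v_g: AudioSignal, h: np.ndarray, h_fs: float | None = None
) -> AudioSignal:
    """Forward-render microphone audio: convolution of the source with ``h``.

    ``h`` is a sampled impulse response; if ``h_fs`` is given it must match
    the source sampling rate.  Output length is ``len(v) + len(h) - 1``.
    """
    if h_fs is not None and not np.isclose(h_fs, v_g.fs):
        raise ValueError(f"sampling-rate mismatch: {h_fs} != {v_g.fs}")
    h = np.asarray(h, dtype=float)
    y = np.convolve(v_g.samples, h)
    return AudioSignal(samples=y, fs=v_g.fs, calibration=v_g.calibration, f_o=v_g.f_o)


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------


def write_wav(path, sig: AudioSignal, seed: int | None = None) -> None:
    """Write float WAV plus a JSON sidecar with calibration and f_o."""
    wavfile.write(path, int(round(sig.fs)), sig.samples.astype(np.float32))
    meta = {"f_o": sig.f_o, "calibration": sig.calibration, "seed": seed}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)


def read_wav(path) -> AudioSignal:
    fs, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    meta = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return AudioSignal(
        samples=np.asarray(data, dtype=float),
        fs=float(fs),
        calibration=float(meta.get("calibration") or 1.0),
        f_o=meta.get("f_o"),
    )


def export_stl(path, mesh: VolumeMesh) -> None:
    """Write the boundary surface as STL (via trimesh)."""
    import trimesh

    faces = np.concatenate(list(mesh.oriented_patches().values()))
    tm = trimesh.Trimesh(vertices=mesh.nodes / 1e-3, faces=faces, process=False)
    tm.export(path)
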