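"""Morphometry of vocal-tract cavities: sub-volumes, OP/HP ratio, length.

The cavity is dissected into seven anatomically motivated sub-volumes —
oropharynx front/rear (OPf, OPr), upper/lower hypopharynx (HPu, HPl),
epilarynx tube (ET), piriform sinus (SP) and ventricular volume (VV) — by
an ordered set of named cutting planes supplied in a
:class:`DissectionConfig` (the anatomical landmarks that define the planes
are identified manually, so the configuration is explicit data rather than
an automatic detection step; synthetic and study meshes share one code
path).  Tetrahedra are assigned to compartments by centroid, which
conserves the total volume exactly.

Derived quantities: OP = OPf + OPr, HP = HPu + HPl + ET + SP + VV, bulk
volume V = OP + HP, the dimensionless OP/HP ratio (> 1 for megaphone-like
tracts, < 1 for inverted-megaphone ones), and the tract length L from the
glottal-patch centroid to the lip-patch centroid along a smoothed shortest
interior path.  Reports use cm/cm^3 to match conventional tables; the mesh
itself stays in SI metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .meshdata import MeshError, VolumeMesh, tet_volumes
from .mshio import read_msh

__all__ = [
    "SubvolumeSet",
    "MorphometryRecord",
    "DissectionConfig",
    "Plane",
    "load_mesh",
    "dissect",
    "tract_length",
    "morphometry",
]

SUBVOLUME_LABELS = ("OPf", "OPr", "HPu", "HPl", "ET", "SP", "VV")
M3_TO_CM3 = 1e6
M_TO_CM = 1e2


@dataclass
class SubvolumeSet:
    """Seven sub-volumes in cm^3 (zero for compartments a shape lacks)."""

    OPf: float = 0.0
    OPr: float = 0.0
    HPu: float = 0.0
    HPl: float = 0.0
    ET: float = 0.0
    SP: float = 0.0
    VV: float = 0.0

    @property
    def OP(self) -> float:
        return self.OPf + self.OPr

    @property
    def HP(self) -> float:
        return self.HPu + self.HPl + self.ET + self.SP + self.VV

    @property
    def V(self) -> float:
        return self.OP + self.HP

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in SUBVOLUME_LABELS}
        d.update(OP=self.OP, HP=self.HP, V=self.V)
        return d


@dataclass
class MorphometryRecord:
    """Tract length L (cm), bulk volume V (cm^3) and OP/HP ratio."""

    L: float
    V: float
    op_hp_ratio: float | None  # None when HP = 0 (undefined)


@dataclass
class Plane:
    """Oriented cutting plane: points with (x - point) . normal >= 0 lie above."""

    name: str
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError(f"plane {self.name!r} has zero normal")
        self.normal = self.normal / n

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts) - self.point) @ self.normal


@dataclass
class DissectionConfig:
    """Ordered cutting planes and the compartment-to-label mapping.

    Compartment ``i`` collects the tets below plane ``i`` (negative signed
    distance) that are not below any earlier plane; the final compartment
    collects everything above all planes.  ``compartments`` therefore names
    ``len(planes) + 1`` labels, each one of the seven sub-volume labels.
    """

    planes: list[Plane] = field(default_factory=list)
    compartments: list[str] = field(default_factory=lambda: ["OPf"])

    def __post_init__(self):
        if len(self.compartments) != len(self.planes) + 1:
            raise ValueError("need exactly len(planes) + 1 compartment labels")
        unknown = set(self.compartments) - set(SUBVOLUME_LABELS)
        if unknown:
            raise ValueError(f"unknown sub-volume labels: {sorted(unknown)}")
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("compartment labels must be distinct")

    @classmethod
    def from_json(cls, path) -> "DissectionConfig":
        with open(path) as fh:
            data = json.load(fh)
        planes = [Plane(p["name"], p["point"], p["normal"]) for p in data["planes"]]
        return cls(planes=planes, compartments=list(data["compartments"]))

    def to_json(self, path) -> None:
        data = {
            "planes": [
                {"name": p.name, "point": p.point.tolist(), "normal": p.normal.tolist()}
                for p in self.planes
            ],
            "compartments": self.compartments,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def axial_split(cls, x_cut: float, front: str = "OPf", back: str = "HPl"):
        """Single cut perpendicular to the tract axis at ``x_cut`` (m).

        The lips side (x > x_cut) maps to ``front`` (oral compartment), the
        glottis side to ``back`` (hypopharyngeal compartment) — the minimal
        configuration that defines an OP/HP ratio for synthetic tubes.
        """
        return cls(
            planes=[Plane("oro-hypo boundary", [x_cut, 0.0, 0.0], [1.0, 0.0, 0.0])],
            compartments=[back, front],
        )


def load_mesh(
    path, patch_spec: str | dict | None = None, element_size: float = 0.0015
) -> VolumeMesh:
    """Load a tagged cavity mesh from MSH, or tetrahedralize a surface STL.

    MSH files must carry the three physical surface groups ``glottis``,
    ``wall`` and ``lips``.  STL files carry no tags, so a ``patch_spec``
    auto-detect rule is required: ``"axial"`` tags the planar cap at minimum
    x as glottis and the cap at maximum x as lips.  The STL interior is
    re-meshed into tets on a voxel grid of the given element size
    (millimetre coordinates assumed in the file, as exported here).
    """
    path = str(path)
    if path.lower().endswith(".msh"):
        mesh = read_msh(path)
        mesh.validate()
        return mesh
    if not path.lower().endswith(".stl"):
        raise MeshError(f"unsupported mesh format: {path}")
    if patch_spec is None:
        raise MeshError("patches unresolved: STL carries no tags and no "
                        "auto-detect rule was given")
    mode = patch_spec if isinstance(patch_spec, str) else patch_spec.get("mode")
    if mode != "axial":
        raise MeshError(f"patches unresolved: unknown auto-detect rule {mode!r}")
    import trimesh

    from .meshdata import mesh_contains
    from .synthetic import voxel_mesh
    from .synthetic import _classify_patches  # staircase tagging by axial planes

    tm = trimesh.load(path)
    if not tm.is_watertight:
        raise MeshError(f"{path}: surface is not watertight")
    verts = np.asarray(tm.vertices, dtype=float) * 1e-3  # mm -> m
    faces = np.asarray(tm.faces, dtype=int)
    lo, hi = verts.min(axis=0), verts.max(axis=0)

    def inside(p):
        return mesh_contains(p, verts, faces)

    nodes, tets = voxel_mesh(inside, (lo, hi), element_size)
    # shift so the glottal plane sits at x = 0 for classification
    x0 = nodes[:, 0].min()
    nodes = nodes - np.array([x0, 0.0, 0.0])
    L = nodes[:, 0].max()
    patches = _classify_patches(nodes, tets, L)
    lips_nodes = nodes[np.unique(patches["lips"])]
    aperture = float(np.sqrt((lips_nodes[:, 1:] ** 2).sum(axis=1).max()))
    mesh = VolumeMesh(nodes=nodes, tets=tets, patches=patches,
                      r_l=0.6 * aperture, name=path.rsplit("/", 1)[-1])
    mesh.validate()
    return mesh


def dissect(mesh: VolumeMesh, cfg: DissectionConfig) -> SubvolumeSet:
    """Assign tetrahedra to labelled compartments by centroid.

    The per-label volumes sum to the bulk mesh volume exactly (no tet is
    split).  A label that receives no tets gets volume zero — legitimate
    for shapes without that anatomical compartment.
    """
    vols = tet_volumes(mesh.nodes, mesh.tets)
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    assigned = np.full(len(vols), len(cfg.planes), dtype=int)
    remaining = np.ones(len(vols), dtype=bool)
    for i, plane in enumerate(cfg.planes):
        below = plane.signed_distance(centroids) < 0
        take = remaining & below
        assigned[take] = i
        remaining &= ~take
    out = SubvolumeSet()
    for i, label in enumerate(cfg.compartments):
        setattr(out, label, float(vols[assigned == i].sum()) * M3_TO_CM3)
    return out


def _tet_adjacency(tets: np.ndarray) -> sp.csr_matrix:
    faces = np.concatenate(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    ks, os_ = key[order], owner[order]
    eq = (ks[1:] == ks[:-1]).all(axis=1)
    i, j = os_[:-1][eq], os_[1:][eq]
    n = len(tets)
    return sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()


def tract_length(
    mesh: VolumeMesh,
    smoothing_iterations: int = 20,
    medial_weight: float = 2.0,
    resample_step_edges: float = 2.0,
) -> float:
    """Centerline length from glottis to lips, in cm.

    A shortest path between the patch-centroid tets is traced on the tet
    adjacency graph with edge weights penalized by inverse distance to the
    wall (exponent ``medial_weight``), which keeps the path on the duct's
    medial axis instead of letting it cut corners.  The centroid chain is
    lightly Laplacian-smoothed with fixed endpoints and resampled at about
    two mean edge lengths before measuring, which removes the mesh-scale
    zigzag that would otherwise inflate the length.  Edge weights and
    endpoint selection are quantized so the result is invariant under rigid
    motion of the mesh.  Fails on a cavity disconnected between the patches.
    """
    from scipy.spatial import cKDTree

    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    g_c = mesh.patch_centroid("glottis")
    l_c = mesh.patch_centroid("lips")
    scale = float(np.linalg.norm(mesh.nodes.max(0) - mesh.nodes.min(0)))
    q = 1e-9 * scale
    dg = np.round(np.linalg.norm(centroids - g_c, axis=1) / q) * q
    dl = np.round(np.linalg.norm(centroids - l_c, axis=1) / q) * q
    start, end = int(np.argmin(dg)), int(np.argmin(dl))
    wall_centers = mesh.nodes[mesh.patches["wall"]].mean(axis=1)
    d_wall, _ = cKDTree(wall_centers).query(centroids)
    adj = _tet_adjacency(mesh.tets).tocoo()
    d = np.linalg.norm(centroids[adj.row] - centroids[adj.col], axis=1)
    depth = 0.5 * (d_wall[adj.row] + d_wall[adj.col]) + 1e-12
    w = d * (d_wall.max() / depth) ** medial_weight
    w = np.round(w / q) * q
    graph = sp.coo_matrix((w, (adj.row, adj.col)), shape=adj.shape).tocsr()
    dist, pred = dijkstra(
        graph, directed=False, indices=start, return_predecessors=True
    )
    if not np.isfinite(dist[end]):
        raise MeshError("cavity is disconnected between glottis and lips")
    chain = [end]
    while chain[-1] != start:
        chain.append(int(pred[chain[-1]]))
    pts = np.concatenate([[l_c], centroids[chain], [g_c]])
    for _ in range(smoothing_iterations):
        pts[1:-1] = 0.5 * pts[1:-1] + 0.25 * (pts[:-2] + pts[2:])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    step = resample_step_edges * mesh.mean_edge_length()
    n = max(2, int(np.ceil(s[-1] / step)))
    si = np.linspace(0.0, s[-1], n + 1)
    rp = np.stack([np.interp(si, s, pts[:, k]) for k in range(3)], axis=1)
    return float(np.linalg.norm(np.diff(rp, axis=0), axis=1).sum()) * M_TO_CM


def morphometry(sub: SubvolumeSet, L_cm: float) -> MorphometryRecord:
    """Combine sub-volumes and tract length into the summary record."""
    ratio = sub.OP / sub.HP if sub.HP > 0 else None
    return MorphometryRecord(L=L_cm, V=sub.V, op_hp_ratio=ratio)
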