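"""Tagged tetrahedral cavity meshes.

The acoustic domain is the air-filled vocal-tract cavity, a tetrahedral mesh
whose closed boundary is partitioned into exactly three patches:

``glottis``
    the source plane at the vocal folds (flat disc at the caudal end),
``wall``
    the tissue wall of the tract,
``lips``
    the radiating aperture at the mouth opening.

All coordinates are SI metres internally; mesh files written by this package
carry millimetres (converted on read/write).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATCH_NAMES = ("glottis", "wall", "lips")


class MeshError(ValueError):
    """Raised when a mesh violates a structural invariant."""


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    b = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Reorder tets in place so all signed volumes are positive."""
    vol = tet_volumes(nodes, tets)
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles (faces belonging to one tet only).

    Face orientation follows the owning tet so normals point out of the
    domain when tets are positively oriented.
    """
    # local faces with outward winding for a positively oriented tet
    f = np.concatenate(
        [
            tets[:, [0, 2, 1]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [1, 2, 3]],
        ]
    )
    key = np.sort(f, axis=1)
    order = np.lexsort(key.T)
    key_sorted = key[order]
    dup_prev = np.zeros(len(key), dtype=bool)
    eq = (key_sorted[1:] == key_sorted[:-1]).all(axis=1)
    dup_prev[1:] = eq
    dup_next = np.zeros(len(key), dtype=bool)
    dup_next[:-1] = eq
    unique = ~(dup_prev | dup_next)
    return f[order[unique]]


@dataclass
class VolumeMesh:
    """Watertight tetrahedral cavity with three tagged boundary patches.

    Parameters
    ----------
    nodes : (N, 3) float array, metres
    tets : (M, 4) int array
    patches : mapping of patch name to (K, 3) int triangle arrays; keys must
        be exactly ``glottis``, ``wall`` and ``lips``.
    r_l : equivalent radiating-sphere radius of the lip opening, metres.
    """

    nodes: np.ndarray
    tets: np.ndarray
    patches: dict[str, np.ndarray]
    r_l: float
    name: str = "mesh"
    _cache: dict = field(default_factory=dict, repr=False)

    # -- derived geometry ---------------------------------------------------
    @property
    def volume(self) -> float:
        """Bulk cavity volume in m^3."""
        return float(tet_volumes(self.nodes, self.tets).sum())

    def patch_area(self, patch: str) -> float:
        return float(triangle_areas(self.nodes, self.patches[patch]).sum())

    @property
    def A_g(self) -> float:
        return self.patch_area("glottis")

    @property
    def A_l(self) -> float:
        return self.patch_area("lips")

    def patch_centroid(self, patch: str) -> np.ndarray:
        """Area-weighted centroid of a patch, metres."""
        tris = self.patches[patch]
        areas = triangle_areas(self.nodes, tris)
        centers = self.nodes[tris].mean(axis=1)
        return (centers * areas[:, None]).sum(axis=0) / areas.sum()

    def patch_center_node(self, patch: str) -> int:
        """Global index of the node nearest the patch's area-weighted centroid."""
        c = self.patch_centroid(patch)
        idx = np.unique(self.patches[patch])
        d = np.linalg.norm(self.nodes[idx] - c, axis=1)
        return int(idx[np.argmin(d)])

    def mean_edge_length(self) -> float:
        e = np.concatenate(
            [self.tets[:, [0, 1]], self.tets[:, [0, 2]], self.tets[:, [0, 3]],
             self.tets[:, [1, 2]], self.tets[:, [1, 3]], self.tets[:, [2, 3]]]
        )
        v = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return float(np.linalg.norm(v, axis=1).mean())

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise :class:`MeshError` on defect.

        Invariants: positive tet volumes, the three patches exist and are
        non-empty, their union equals the boundary of the tet mesh (hence the
        surface is closed/watertight), and patch areas are positive.
        """
        if not np.isfinite(self.nodes).all():
            raise MeshError("non-finite node coordinates")
        vol = tet_volumes(self.nodes, self.tets)
        if (vol <= 0).any():
            raise MeshError(f"{int((vol <= 0).sum())} non-positive tet volumes")
        missing = [p for p in PATCH_NAMES if p not in self.patches]
        if missing:
            raise MeshError(f"missing patch tag(s): {missing}")
        for p in ("glottis", "lips"):
            if len(self.patches[p]) == 0:
                raise MeshError(f"empty patch {p!r}")
        bnd = boundary_faces(self.tets)
        bnd_set = {tuple(x) for x in np.sort(bnd, axis=1).tolist()}
        tagged = np.concatenate([self.patches[p] for p in PATCH_NAMES])
        tag_set = {tuple(x) for x in np.sort(tagged, axis=1).tolist()}
        if len(tagged) != len(tag_set):
            raise MeshError("duplicate triangles across patch tags")
        if bnd_set != tag_set:
            raise MeshError(
                "patch union does not match the mesh boundary "
                f"({len(tag_set)} tagged vs {len(bnd_set)} boundary faces); "
                "surface is not watertight or tags are incomplete"
            )
        if self.A_g <= 0 or self.A_l <= 0:
            raise MeshError("non-positive patch area")
        if self.r_l <= 0:
            raise MeshError("non-positive lip radius r_l")

    def oriented_patches(self) -> dict[str, np.ndarray]:
        """Patch triangles rewound to match outward boundary orientation."""
        bnd = boundary_faces(self.tets)
        lookup = {tuple(sorted(t)): t for t in bnd.tolist()}
        out = {}
        for p, tris in self.patches.items():
            out[p] = np.array(
                [lookup[tuple(sorted(t))] for t in tris.tolist()], dtype=int
            ).reshape(-1, 3)
        return out


def mesh_contains(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> np.ndarray:
    """Even-odd point-in-solid test for a closed triangle surface.

    Casts a +z ray from each query point and counts triangle crossings
    (vectorized over triangles in point batches).  Query x/y coordinates are
    jittered by a tiny irrational offset so rays do not pass exactly through
    triangle edges of axis-aligned meshes.
    """
    points = np.asarray(points, dtype=float)
    tri = vertices[faces]  # (T, 3, 3)
    scale = float(np.ptp(vertices, axis=0).max())
    eps = 1e-7 * scale
    p1, p2, p3 = tri[:, 0], tri[:, 1], tri[:, 2]
    out = np.zeros(len(points), dtype=bool)
    batch = max(1, int(5e6 // max(len(faces), 1)))
    for s in range(0, len(points), batch):
        q = points[s : s + batch].copy()
        q[:, 0] += eps * np.sqrt(2.0)
        q[:, 1] += eps * np.sqrt(3.0)
        x, y, z = q[:, 0:1], q[:, 1:2], q[:, 2:3]
        # 2-D signed areas of the projected sub-triangles
        d1 = (p2[:, 0] - p1[:, 0]) * (y - p1[:, 1]) - (p2[:, 1] - p1[:, 1]) * (x - p1[:, 0])
        d2 = (p3[:, 0] - p2[:, 0]) * (y - p2[:, 1]) - (p3[:, 1] - p2[:, 1]) * (x - p2[:, 0])
        d3 = (p1[:, 0] - p3[:, 0]) * (y - p3[:, 1]) - (p1[:, 1] - p3[:, 1]) * (x - p3[:, 0])
        inside_xy = ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | (
            (d1 <= 0) & (d2 <= 0) & (d3 <= 0)
        )
        # z of the triangle plane at (x, y), via barycentric weights
        area = d1 + d2 + d3
        ok = inside_xy & (np.abs(area) > 1e-30)
        with np.errstate(invalid="ignore", divide="ignore"):
            zt = (
                d2 * p1[:, 2] + d3 * p2[:, 2] + d1 * p3[:, 2]
            ) / np.where(np.abs(area) > 1e-30, area, np.nan)
        crossings = (ok & (zt > z)).sum(axis=1)
        out[s : s + batch] = (crossings % 2) == 1
    return out
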