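"""Minimal Gmsh MSH v4.1 (ASCII) reader/writer for tagged cavity meshes.

Writes one 3-D entity holding the tetrahedra and one 2-D entity per boundary
patch, with physical surface groups named exactly ``glottis``, ``wall`` and
``lips`` and a physical volume ``cavity``.  Coordinates are stored in
millimetres in the file and converted to metres on read.

Only the subset of the format emitted here is supported on read (enough to
round-trip this package's meshes and meshes tagged the same way by Gmsh).
"""

from __future__ import annotations

import numpy as np

from .meshdata import MeshError, VolumeMesh, PATCH_NAMES

MM = 1e-3

_PATCH_PHYS = {"glottis": 1, "wall": 2, "lips": 3}
_VOL_PHYS = 4


def write_msh(path, mesh: VolumeMesh) -> None:
    patches = mesh.oriented_patches()
    lines: list[str] = []
    add = lines.append
    add("$MeshFormat")
    add("4.1 0 8")
    add("$EndMeshFormat")
    # stash r_l and name in a comment-like metadata section gmsh ignores
    add("$Comments")
    add(f"tractacoustics r_l_mm {mesh.r_l / MM:.9g} name {mesh.name}")
    add("$EndComments")
    add("$PhysicalNames")
    add("4")
    for pname, tag in _PATCH_PHYS.items():
        add(f'2 {tag} "{pname}"')
    add(f'3 {_VOL_PHYS} "cavity"')
    add("$EndPhysicalNames")
    # entities: 0 points, 3 surfaces, 1 volume
    xyz = mesh.nodes / MM
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    add("$Entities")
    add("0 0 3 1")
    for pname, tag in _PATCH_PHYS.items():
        add(
            f"{tag} {lo[0]:.9g} {lo[1]:.9g} {lo[2]:.9g} "
            f"{hi[0]:.9g} {hi[1]:.9g} {hi[2]:.9g} 1 {tag} 0"
        )
    add(
        f"1 {lo[0]:.9g} {lo[1]:.9g} {lo[2]:.9g} "
        f"{hi[0]:.9g} {hi[1]:.9g} {hi[2]:.9g} 1 {_VOL_PHYS} 3 1 2 3"
    )
    add("$EndEntities")
    n = len(xyz)
    add("$Nodes")
    add(f"1 {n} 1 {n}")
    add(f"3 1 0 {n}")
    for i in range(1, n + 1):
        add(str(i))
    for p in xyz:
        add(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    add("$EndNodes")
    n_elem = sum(len(patches[p]) for p in PATCH_NAMES) + len(mesh.tets)
    add("$Elements")
    add(f"4 {n_elem} 1 {n_elem}")
    eid = 1
    for pname, tag in _PATCH_PHYS.items():
        tris = patches[pname]
        add(f"2 {tag} 2 {len(tris)}")
        for t in tris + 1:
            add(f"{eid} {t[0]} {t[1]} {t[2]}")
            eid += 1
    add(f"3 1 4 {len(mesh.tets)}")
    for t in mesh.tets + 1:
        add(f"{eid} {t[0]} {t[1]} {t[2]} {t[3]}")
        eid += 1
    add("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _sections(text: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    cur = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$End"):
            cur = None
        elif line.startswith("$"):
            cur = line[1:]
            out[cur] = []
        elif cur is not None:
            out[cur].append(line)
    return out


def read_msh(path) -> VolumeMesh:
    with open(path) as fh:
        sec = _sections(fh.read())
    if "MeshFormat" not in sec or not sec["MeshFormat"][0].startswith("4.1"):
        raise MeshError(f"{path}: not an ASCII MSH v4.1 file")
    r_l = None
    name = "mesh"
    for line in sec.get("Comments", []):
        tok = line.split()
        if tok[:1] == ["tractacoustics"]:
            r_l = float(tok[2]) * MM
            name = tok[4] if len(tok) > 4 else name
    # physical names -> patch names
    phys2d = {}
    for line in sec.get("PhysicalNames", [])[1:]:
        dim, tag, pname = line.split(None, 2)
        if int(dim) == 2:
            phys2d[int(tag)] = pname.strip('"')
    # entities: surface entity tag -> physical tag
    ent_phys = {}
    hdr = sec["Entities"][0].split()
    np_, nc, ns, nv = (int(x) for x in hdr)
    rows = sec["Entities"][1:]
    for line in rows[np_ + nc : np_ + nc + ns]:
        tok = line.split()
        etag = int(tok[0])
        nphys = int(tok[7])
        if nphys >= 1:
            ent_phys[etag] = int(tok[8])
    # nodes
    it = iter(sec["Nodes"])
    nblocks = int(next(it).split()[0])
    tags: list[int] = []
    coords: list[list[float]] = []
    for _ in range(nblocks):
        bn = int(next(it).split()[3])
        btags = [int(next(it)) for _ in range(bn)]
        bxyz = [[float(v) for v in next(it).split()[:3]] for _ in range(bn)]
        tags.extend(btags)
        coords.extend(bxyz)
    tag2idx = {t: i for i, t in enumerate(tags)}
    nodes = np.asarray(coords, dtype=float) * MM
    # elements
    it = iter(sec["Elements"])
    nblocks = int(next(it).split()[0])
    patches: dict[str, list[list[int]]] = {p: [] for p in PATCH_NAMES}
    tets: list[list[int]] = []
    for _ in range(nblocks):
        dim, etag, etype, count = (int(x) for x in next(it).split())
        for _ in range(count):
            tok = next(it).split()
            conn = [tag2idx[int(t)] for t in tok[1:]]
            if etype == 2:  # triangle
                pname = phys2d.get(ent_phys.get(etag, -1))
                if pname in patches:
                    patches[pname].append(conn)
            elif etype == 4:  # tetrahedron
                tets.append(conn)
    missing = [p for p in PATCH_NAMES if not patches[p]]
    if missing:
        raise MeshError(f"{path}: missing patch tag(s): {missing}")
    if not tets:
        raise MeshError(f"{path}: no tetrahedra")
    mesh = VolumeMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=int),
        patches={p: np.asarray(v, dtype=int) for p, v in patches.items()},
        r_l=r_l if r_l is not None else 1.0,
        name=name,
    )
    if r_l is None:
        # fall back: equivalent circular radius of the lip patch
        mesh.r_l = float(np.sqrt(mesh.A_l / np.pi))
    return mesh
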