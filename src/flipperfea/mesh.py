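"""Tetrahedral mesh container and mesh I/O.

Units are millimetres for coordinates and MPa (= N/mm^2) for any stress
data attached to a mesh, so that forces in newtons need no conversion.

Conventions
-----------
* node and element indices are 0-based internally; the 1-based Gmsh
  convention is translated at the file boundary.
* coordinate frame: +x runs proximal -> distal along the bone long axis,
  +y is anterior, +z is dorsal.
* linear elements are 4-node tetrahedra; quadratic elements are 10-node
  tetrahedra with midside nodes at straight-edge midpoints, ordered per
  VTK (corners 0-3, then midsides on edges 01, 12, 02, 03, 13, 23).
"""

from __future__ import annotations

import io
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TetMesh",
    "SurfaceMesh",
    "Material",
    "read_surface",
    "write_surface",
    "read_volume",
    "write_volume",
    "read_msh",
    "write_msh",
    "read_vtu",
    "write_vtu",
    "scale_to_physical",
    "tet_volumes",
    "radius_ratio",
]

# VTK tet10 midside nodes lie on these corner pairs, in this order.
TET10_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]

# Gmsh orders tet10 midsides on edges 01,12,02,03,23,13 -> permutation
# from internal (VTK) order to gmsh order and back.
_GMSH_FROM_VTK = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
_VTK_FROM_GMSH = _GMSH_FROM_VTK  # the permutation is an involution


@dataclass
class Material:
    """Linear-elastic isotropic material (E in MPa, dimensionless nu)."""

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError(f"Young's modulus must be > 0, got {self.young_modulus}")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {self.poisson_ratio}")


@dataclass
class SurfaceMesh:
    """Indexed triangle surface (welded, possibly non-watertight)."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    watertight: bool = False

    @property
    def euler_characteristic(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 0, 2]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + len(self.faces)


@dataclass
class TetMesh:
    """Volumetric tetrahedral mesh with region tags and named node sets."""

    nodes: np.ndarray  # (N, 3) float, mm
    elements: np.ndarray  # (M, 4) or (M, 10) int
    region: np.ndarray = field(default=None)  # (M,) str, e.g. "bone"/"cartilage"
    node_sets: dict = field(default_factory=dict)  # name -> (k,) int array

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise ValueError("elements must be (M,4) or (M,10)")
        if self.region is None:
            self.region = np.full(len(self.elements), "bone", dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        if len(self.region) != len(self.elements):
            raise ValueError("one region tag per element required")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references nonexistent nodes")
        for name, idx in self.node_sets.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.nodes)):
                raise ValueError(f"node set {name!r} references nonexistent nodes")
            self.node_sets[name] = idx
        self._surface_cache = None

    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def is_quadratic(self) -> bool:
        return self.elements.shape[1] == 10

    @property
    def corners(self) -> np.ndarray:
        """Corner connectivity (M, 4), identical for tet4 and tet10."""
        return self.elements[:, :4]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.corners)

    def fix_orientation(self) -> int:
        """Reorder nodes of negative-volume tets in place; return count fixed."""
        vol = self.volumes()
        bad = np.where(vol <= 0)[0]
        if bad.size == 0:
            return 0
        if self.is_quadratic:
            perm = [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]
        else:
            perm = [0, 2, 1, 3]
        self.elements[bad] = self.elements[bad][:, perm]
        self._surface_cache = None
        return int(bad.size)

    def surface(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary triangles (corner-node indices) and parent element ids.

        Triangles are oriented outward.  Cached until the mesh mutates.
        """
        if self._surface_cache is not None:
            return self._surface_cache
        c = self.corners
        # local faces oriented outward for a positive-volume tet
        local = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        faces = c[:, local].reshape(-1, 3)  # (4M, 3)
        parents = np.repeat(np.arange(self.n_elements), 4)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        boundary = counts[inv] == 1
        self._surface_cache = (faces[boundary], parents[boundary])
        return self._surface_cache

    def surface_nodes(self) -> np.ndarray:
        """All node indices on the boundary (includes midside nodes)."""
        tris, parents = self.surface()
        idx = set(np.unique(tris).tolist())
        if self.is_quadratic:
            emap = quadratic_edge_map(self)
            for tri in tris:
                for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])):
                    m = emap.get((min(a, b), max(a, b)))
                    if m is not None:
                        idx.add(int(m))
        return np.array(sorted(idx), dtype=np.int64)

    def outward_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-boundary-triangle outward unit normals and triangle areas."""
        tris, _ = self.surface()
        p = self.nodes[tris]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        area = 0.5 * np.linalg.norm(n, axis=1)
        n = n / (2.0 * area)[:, None]
        return n, area

    def node_normals(self) -> dict:
        """Area-weighted outward normal per surface corner node."""
        tris, _ = self.surface()
        normals, areas = self.outward_normals()
        acc = {}
        for t, n, a in zip(tris, normals, areas):
            for v in t:
                acc.setdefault(int(v), np.zeros(3))
                acc[int(v)] += n * a
        return {v: n / np.linalg.norm(n) for v, n in acc.items()}

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.nodes.copy(),
            self.elements.copy(),
            self.region.copy(),
            {k: v.copy() for k, v in self.node_sets.items()},
        )


# ---------------------------------------------------------------------- #
# geometry helpers


def tet_volumes(nodes: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra given (M,4) corner connectivity."""
    p = nodes[corners]
    return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


def radius_ratio(mesh: TetMesh) -> np.ndarray:
    """Per-element quality 3*r_in/R_circ, equal to 1 for a regular tet."""
    p = mesh.nodes[mesh.corners]
    v = np.abs(tet_volumes(mesh.nodes, mesh.corners))
    # total face area
    combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    area = np.zeros(len(p))
    for i, j, k in combos:
        area += 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1
        )
    r_in = 3.0 * v / area
    # circumradius: solve 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2
    a = 2.0 * (p[:, 1:] - p[:, :1])
    b = (p[:, 1:] ** 2).sum(-1) - (p[:, :1] ** 2).sum(-1)
    centers = np.linalg.solve(a, b[..., None])[..., 0]
    r_circ = np.linalg.norm(centers - p[:, 0], axis=1)
    return 3.0 * r_in / r_circ


def quadratic_edge_map(mesh: TetMesh) -> dict:
    """Map (corner_lo, corner_hi) -> midside node index for a tet10 mesh."""
    if not mesh.is_quadratic:
        raise ValueError("mesh is not quadratic")
    emap = {}
    for el in mesh.elements:
        for (la, lb), mid in zip(TET10_EDGES, el[4:]):
            a, b = int(el[la]), int(el[lb])
            emap[(min(a, b), max(a, b))] = int(mid)
    return emap


def to_quadratic(mesh: TetMesh) -> TetMesh:
    """Insert straight-edge midpoints, turning tet4 into tet10 (SOLID92-style)."""
    if mesh.is_quadratic:
        return mesh.copy()
    c = mesh.corners
    edges = np.concatenate([np.sort(c[:, e], axis=1) for e in TET10_EDGES], axis=0)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mids = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    mid_idx = inv.reshape(6, -1).T + mesh.n_nodes  # (M, 6)
    elements = np.concatenate([c, mid_idx], axis=1)
    return TetMesh(
        np.vstack([mesh.nodes, mids]),
        elements,
        mesh.region.copy(),
        {k: v.copy() for k, v in mesh.node_sets.items()},
    )


def scale_to_physical(mesh: TetMesh, reference_length: float, axis: int = 0) -> TetMesh:
    """Uniformly scale so the bounding-box extent along ``axis`` equals
    ``reference_length`` (mm)."""
    if reference_length <= 0:
        raise ValueError("reference_length must be > 0")
    extent = mesh.nodes[:, axis].max() - mesh.nodes[:, axis].min()
    if extent <= 0:
        raise ValueError(f"mesh has zero extent along axis {axis}")
    out = mesh.copy()
    out.nodes *= reference_length / extent
    return out


# ---------------------------------------------------------------------- #
# STL surface I/O (via trimesh)


def read_surface(path, weld_tolerance: float | None = None) -> SurfaceMesh:
    """Read an STL (binary or ASCII) and weld the triangle soup.

    ``weld_tolerance`` defaults to 1e-6 of the bounding-box diagonal.
    Emits a warning (not an error) if the welded surface is not watertight.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    tm = _trimesh.load_mesh(str(path), process=False)
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(faces) == 0:
        raise IOError(f"empty or unreadable STL: {path}")
    diag = np.linalg.norm(verts.max(0) - verts.min(0))
    tol = weld_tolerance if weld_tolerance is not None else 1e-6 * diag
    if tol <= 0:
        tol = 1e-12
    keys = np.round(verts / tol).astype(np.int64)
    uniq, inv = np.unique(keys, axis=0, return_index=False, return_inverse=True)
    # representative coordinates: first occurrence of each key
    order = np.argsort(inv, kind="stable")
    first = np.zeros(len(uniq), dtype=np.int64)
    seen = np.full(len(uniq), -1, dtype=np.int64)
    for i in order:
        if seen[inv[i]] < 0:
            seen[inv[i]] = i
    first = seen
    welded = verts[first]
    new_faces = inv[faces]
    # drop degenerate triangles
    good = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[good]
    edges = np.sort(new_faces[:, [0, 1, 1, 2, 0, 2]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    watertight = bool(len(counts) and np.all(counts == 2))
    if not watertight:
        warnings.warn(f"surface {path.name} is not watertight", stacklevel=2)
    return SurfaceMesh(welded, new_faces, watertight)


def write_surface(surface: SurfaceMesh, path) -> None:
    tm = _trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    tm.export(str(path))


# ---------------------------------------------------------------------- #
# Gmsh MSH I/O

_MSH_TET4, _MSH_TET10, _MSH_POINT = 4, 11, 15


def write_msh(mesh: TetMesh, path, version: str = "4.1") -> None:
    """Write a TetMesh as ASCII Gmsh MSH v2.2 or v4.1.

    Regions become dim-3 physical groups; named node sets are stored as
    point elements carrying dim-0 physical names.
    """
    if version not in ("2.2", "4.1"):
        raise ValueError("supported MSH versions: 2.2, 4.1")
    regions = sorted(set(mesh.region.tolist()))
    region_tag = {r: i + 1 for i, r in enumerate(regions)}
    set_names = sorted(mesh.node_sets)
    set_tag = {s: len(regions) + i + 1 for i, s in enumerate(set_names)}
    conn = mesh.elements
    if mesh.is_quadratic:
        conn = conn[:, _GMSH_FROM_VTK]
    etype = _MSH_TET10 if mesh.is_quadratic else _MSH_TET4

    buf = io.StringIO()
    w = buf.write
    if version == "2.2":
        w("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        w("$PhysicalNames\n%d\n" % (len(regions) + len(set_names)))
        for r in regions:
            w('3 %d "%s"\n' % (region_tag[r], r))
        for s in set_names:
            w('0 %d "%s"\n' % (set_tag[s], s))
        w("$EndPhysicalNames\n")
        w("$Nodes\n%d\n" % mesh.n_nodes)
        for i, p in enumerate(mesh.nodes):
            w("%d %.17g %.17g %.17g\n" % (i + 1, p[0], p[1], p[2]))
        w("$EndNodes\n")
        n_pts = sum(len(v) for v in mesh.node_sets.values())
        w("$Elements\n%d\n" % (mesh.n_elements + n_pts))
        eid = 1
        for el, reg in zip(conn, mesh.region):
            t = region_tag[reg]
            w("%d %d 2 %d %d %s\n" % (eid, etype, t, t, " ".join(str(n + 1) for n in el)))
            eid += 1
        for s in set_names:
            t = set_tag[s]
            for n in mesh.node_sets[s]:
                w("%d 15 2 %d %d %d\n" % (eid, t, t, n + 1))
                eid += 1
        w("$EndElements\n")
    else:  # 4.1
        w("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        w("$PhysicalNames\n%d\n" % (len(regions) + len(set_names)))
        for r in regions:
            w('3 %d "%s"\n' % (region_tag[r], r))
        for s in set_names:
            w('0 %d "%s"\n' % (set_tag[s], s))
        w("$EndPhysicalNames\n")
        lo, hi = mesh.nodes.min(0), mesh.nodes.max(0)
        # entities: one dim-0 entity per node set, one dim-3 entity per region
        w("$Entities\n%d 0 0 %d\n" % (len(set_names), len(regions)))
        for s in set_names:
            w("%d 0 0 0 1 %d\n" % (set_tag[s], set_tag[s]))
        for r in regions:
            w(
                "%d %.17g %.17g %.17g %.17g %.17g %.17g 1 %d 0\n"
                % (region_tag[r], lo[0], lo[1], lo[2], hi[0], hi[1], hi[2], region_tag[r])
            )
        w("$EndEntities\n")
        w("$Nodes\n1 %d 1 %d\n" % (mesh.n_nodes, mesh.n_nodes))
        w("3 %d 0 %d\n" % (region_tag[regions[0]], mesh.n_nodes))
        for i in range(mesh.n_nodes):
            w("%d\n" % (i + 1))
        for p in mesh.nodes:
            w("%.17g %.17g %.17g\n" % (p[0], p[1], p[2]))
        w("$EndNodes\n")
        n_pts = sum(len(v) for v in mesh.node_sets.values())
        # contiguous runs of equal region, so element order survives a round trip
        blocks = []
        start = 0
        for i in range(1, mesh.n_elements + 1):
            if i == mesh.n_elements or mesh.region[i] != mesh.region[start]:
                r = mesh.region[start]
                blocks.append(("3", region_tag[r], etype, np.arange(start, i)))
                start = i
        total = mesh.n_elements + n_pts
        n_blocks = len(blocks) + sum(1 for s in set_names if len(mesh.node_sets[s]))
        w("$Elements\n%d %d 1 %d\n" % (n_blocks, total, total))
        eid = 1
        for dim, tag, et, idx in blocks:
            w("%s %d %d %d\n" % (dim, tag, et, len(idx)))
            for i in idx:
                w("%d %s\n" % (eid, " ".join(str(n + 1) for n in conn[i])))
                eid += 1
        for s in set_names:
            nodes = mesh.node_sets[s]
            if not len(nodes):
                continue
            w("0 %d 15 %d\n" % (set_tag[s], len(nodes)))
            for n in nodes:
                w("%d %d\n" % (eid, n + 1))
                eid += 1
        w("$EndElements\n")
    Path(path).write_text(buf.getvalue())


def _msh_sections(text: str) -> dict:
    out = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j])
                j += 1
            out[name] = body
            i = j + 1
        else:
            i += 1
    return out


def read_msh(path) -> TetMesh:
    """Read an ASCII Gmsh MSH v2.2 or v4.1 file containing tetrahedra."""
    text = Path(path).read_text()
    sec = _msh_sections(text)
    if "MeshFormat" not in sec or "Nodes" not in sec or "Elements" not in sec:
        raise IOError(f"not a valid MSH file: {path}")
    version = sec["MeshFormat"][0].split()[0]
    phys = {}
    for line in sec.get("PhysicalNames", [])[1:]:
        parts = line.split(None, 2)
        if len(parts) == 3:
            phys[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    if version.startswith("2"):
        body = sec["Nodes"]
        n = int(body[0])
        ids, coords = [], []
        for line in body[1 : 1 + n]:
            parts = line.split()
            ids.append(int(parts[0]))
            coords.append([float(x) for x in parts[1:4]])
        id_map = {g: i for i, g in enumerate(ids)}
        nodes = np.array(coords)
        elements, regions, points = [], [], []
        body = sec["Elements"]
        m = int(body[0])
        for line in body[1 : 1 + m]:
            parts = [int(x) for x in line.split()]
            etype, ntags = parts[1], parts[2]
            tags = parts[3 : 3 + ntags]
            rest = parts[3 + ntags :]
            ptag = tags[0] if tags else 0
            if etype in (_MSH_TET4, _MSH_TET10):
                elements.append([id_map[g] for g in rest])
                regions.append(phys.get((3, ptag), str(ptag)))
            elif etype == _MSH_POINT:
                points.append((phys.get((0, ptag), str(ptag)), id_map[rest[0]]))
            else:
                raise IOError(f"unsupported element type {etype} in {path}")
    else:  # 4.x
        body = sec["Nodes"]
        header = body[0].split()
        n_blocks = int(header[0])
        ids, coords = [], []
        k = 1
        for _ in range(n_blocks):
            _, _, _, nb = (int(x) for x in body[k].split())
            k += 1
            tags = [int(body[k + i]) for i in range(nb)]
            k += nb
            for i in range(nb):
                coords.append([float(x) for x in body[k + i].split()[:3]])
            k += nb
            ids.extend(tags)
        id_map = {g: i for i, g in enumerate(ids)}
        nodes = np.array(coords)
        # entity -> physical name
        ent_phys = {}
        ent_lines = sec.get("Entities", [])
        if ent_lines:
            np_, nc, ns, nv = (int(x) for x in ent_lines[0].split())
            k2 = 1
            for _ in range(np_):
                parts = ent_lines[k2].split()
                tag = int(parts[0])
                nphys = int(parts[4]) if len(parts) > 4 else 0
                if nphys:
                    ent_phys[(0, tag)] = int(parts[5])
                k2 += 1
            k2 += nc + ns
            for _ in range(nv):
                parts = ent_lines[k2].split()
                tag = int(parts[0])
                nphys = int(parts[7])
                if nphys:
                    ent_phys[(3, tag)] = int(parts[8])
                k2 += 1
        elements, regions, points = [], [], []
        body = sec["Elements"]
        n_blocks = int(body[0].split()[0])
        k = 1
        for _ in range(n_blocks):
            dim, ent, etype, nb = (int(x) for x in body[k].split())
            k += 1
            for i in range(nb):
                parts = [int(x) for x in body[k + i].split()]
                rest = parts[1:]
                if etype in (_MSH_TET4, _MSH_TET10):
                    elements.append([id_map[g] for g in rest])
                    ptag = ent_phys.get((3, ent), ent)
                    regions.append(phys.get((3, ptag), str(ptag)))
                elif etype == _MSH_POINT:
                    ptag = ent_phys.get((0, ent), ent)
                    points.append((phys.get((0, ptag), str(ptag)), id_map[rest[0]]))
                else:
                    raise IOError(f"unsupported element type {etype} in {path}")
            k += nb

    if not elements:
        raise IOError(f"no tetrahedra found in {path}")
    widths = {len(e) for e in elements}
    if len(widths) != 1:
        raise IOError(f"mixed element orders in {path}")
    elements = np.array(elements, dtype=np.int64)
    if elements.shape[1] == 10:
        elements = elements[:, _VTK_FROM_GMSH]
    node_sets = {}
    for name, idx in points:
        node_sets.setdefault(name, []).append(idx)
    node_sets = {k: np.array(sorted(v), dtype=np.int64) for k, v in node_sets.items()}
    out = TetMesh(nodes, elements, np.array(regions, dtype=object), node_sets)
    out.fix_orientation()
    return out


# ---------------------------------------------------------------------- #
# VTK VTU (ASCII XML) I/O

_VTK_TET4, _VTK_TET10 = 10, 24


def write_vtu(
    mesh: TetMesh,
    path,
    cell_data: dict | None = None,
    point_data: dict | None = None,
) -> None:
    """Write ASCII VTU.  Regions and node sets are stored as Int8 masks
    named ``region:<name>`` (cell data) and ``set:<name>`` (point data);
    extra float arrays may be passed via cell_data/point_data."""
    cd = dict(cell_data or {})
    pd = dict(point_data or {})
    for r in sorted(set(mesh.region.tolist())):
        cd[f"region:{r}"] = (mesh.region == r).astype(np.int8)
    for name, idx in sorted(mesh.node_sets.items()):
        mask = np.zeros(mesh.n_nodes, dtype=np.int8)
        mask[idx] = 1
        pd[f"set:{name}"] = mask

    def arr(name, data, indent="        "):
        data = np.asarray(data)
        if data.dtype.kind in "iu b".replace(" ", ""):
            typ = "Int64" if data.dtype.itemsize > 1 else "Int8"
            fmt = "%d"
        else:
            typ, fmt = "Float64", "%.17g"
        ncomp = data.shape[1] if data.ndim == 2 else 1
        flat = data.reshape(-1)
        body = "\n".join(
            indent + " ".join(fmt % x for x in flat[i : i + 6])
            for i in range(0, len(flat), 6)
        )
        extra = f' NumberOfComponents="{ncomp}"' if ncomp > 1 else ""
        return (
            f'{indent[:-2]}<DataArray type="{typ}" Name="{name}"{extra} format="ascii">\n'
            f"{body}\n{indent[:-2]}</DataArray>\n"
        )

    nper = mesh.elements.shape[1]
    vtk_type = _VTK_TET10 if mesh.is_quadratic else _VTK_TET4
    parts = [
        '<?xml version="1.0"?>\n<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n',
        "  <UnstructuredGrid>\n",
        f'    <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">\n',
        "      <Points>\n",
        arr("Points", mesh.nodes),
        "      </Points>\n      <Cells>\n",
        arr("connectivity", mesh.elements.reshape(-1)),
        arr("offsets", np.arange(1, mesh.n_elements + 1) * nper),
        arr("types", np.full(mesh.n_elements, vtk_type, dtype=np.int64)),
        "      </Cells>\n",
    ]
    if pd:
        parts.append("      <PointData>\n")
        for name, data in pd.items():
            parts.append(arr(name, data))
        parts.append("      </PointData>\n")
    if cd:
        parts.append("      <CellData>\n")
        for name, data in cd.items():
            parts.append(arr(name, data))
        parts.append("      </CellData>\n")
    parts.append("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    Path(path).write_text("".join(parts))


def read_vtu(path, return_data: bool = False):
    """Read an ASCII VTU written by this package (tet4/tet10 cells only)."""
    tree = ET.parse(str(path))
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise IOError(f"no <Piece> in {path}")

    def parse(elem):
        text = elem.text or ""
        typ = elem.get("type", "Float64")
        dtype = np.int64 if typ.startswith("Int") else float
        vals = np.array(text.split(), dtype=dtype)
        ncomp = int(elem.get("NumberOfComponents", "1"))
        return vals.reshape(-1, ncomp) if ncomp > 1 else vals

    pts = parse(piece.find("Points/DataArray"))
    cells = {e.get("Name"): parse(e) for e in piece.findall("Cells/DataArray")}
    types = cells["types"]
    if not np.all(np.isin(types, (_VTK_TET4, _VTK_TET10))):
        raise IOError(f"non-tetrahedral cells in {path}")
    if len(set(types.tolist())) > 1:
        raise IOError(f"mixed cell types in {path}")
    nper = 10 if types[0] == _VTK_TET10 else 4
    conn = cells["connectivity"].reshape(-1, nper)
    pdata = {
        e.get("Name"): parse(e) for e in piece.findall("PointData/DataArray")
    }
    cdata = {e.get("Name"): parse(e) for e in piece.findall("CellData/DataArray")}
    region = np.full(len(conn), "bone", dtype=object)
    for name, mask in cdata.items():
        if name.startswith("region:"):
            region[np.asarray(mask).astype(bool)] = name.split(":", 1)[1]
    node_sets = {
        name.split(":", 1)[1]: np.where(np.asarray(mask).astype(bool))[0]
        for name, mask in pdata.items()
        if name.startswith("set:")
    }
    mesh = TetMesh(pts, conn, region, node_sets)
    mesh.fix_orientation()
    if return_data:
        extra_c = {k: v for k, v in cdata.items() if not k.startswith("region:")}
        extra_p = {k: v for k, v in pdata.items() if not k.startswith("set:")}
        return mesh, extra_c, extra_p
    return mesh


# ---------------------------------------------------------------------- #


def read_volume(path) -> TetMesh:
    """Read a volumetric mesh, dispatching on extension (.msh or .vtu)."""
    path = Path(path)
    if path.suffix.lower() == ".msh":
        return read_msh(path)
    if path.suffix.lower() == ".vtu":
        return read_vtu(path)
    raise IOError(f"unsupported volume mesh format: {path.suffix}")


def write_volume(mesh: TetMesh, path, **kw) -> None:
    path = Path(path)
    if path.suffix.lower() == ".msh":
        write_msh(mesh, path, **kw)
    elif path.suffix.lower() == ".vtu":
        write_vtu(mesh, path, **kw)
    else:
        raise IOError(f"unsupported volume mesh format: {path.suffix}")
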