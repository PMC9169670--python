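"""Deterministic synthetic test geometry: a plesiosaur-like propodial.

The generator emulates the gross shape of a plesiosaur humerus/femur — a
long bone with a rounded proximal head capped by soft articular
cartilage, an oval midshaft cross-section, a dorsal process (tuberosity /
trochanter) and anteroposteriorly expanded distal epicondyles — together
with a girdle-muscle apparatus arranged in agonist/antagonist pairs.  It
exists so the whole pipeline can run and be tested without any scan data.

The bone is a mapped structured grid: a box grid in (x, u, v) is carried
onto oval cross-sections by the standard square-to-disk map, with
analytic axial profiles for the head, the epicondylar expansion, and the
dorsal process; hexahedra are split into six tetrahedra sharing the main
diagonal, which yields a conforming, reproducible mesh without an
external mesher.  The cartilage cap is an extruded proximal layer with
shared nodes (bonded contact).

Coordinate frame: +x proximal -> distal, +y anterior, +z dorsal; the
shoulder/hip joint sits at the proximal end (x = 0), so girdle-muscle
origins live at x < 0 and distal-limb muscle origins at x > shaft length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .loads import FlipperPose, MusclePath
from .mesh import TetMesh

__all__ = [
    "BoneParams",
    "SyntheticCase",
    "generate_bone",
    "generate_muscle_set",
    "generate_case",
    "structured_box",
    "default_poses",
]

ROLES = ("depressor", "elevator", "protractor", "retractor", "rotator", "extensor", "flexor")

# mesher shape factors: angular resolution of the O-grid boundary, axial
# station spacing relative to the pole arc length, and the axial spread of
# the epicondylar flare (relative to the half-span)
_C_FACTOR = 0.25
_DX_FACTOR = 2.0
_LAM_EPI_FACTOR = 0.6

# antagonistic pairing per degree of freedom (rotators pair by sense)
ROLE_PAIRS = (("depressor", "elevator"), ("protractor", "retractor"), ("flexor", "extensor"))


@dataclass
class BoneParams:
    """Geometry of the synthetic propodial (all lengths in mm)."""

    shaft_length: float = 300.0
    shaft_radii: tuple = (30.0, 20.0)  # (anterior a, dorsal b) semi-axes
    head_radius: float = 42.0
    dorsal_process_height: float = 12.0
    dorsal_process_position: float = 0.10  # axial fraction of shaft length
    epicondyle_half_span: float = 52.0
    cartilage_cap_thickness: float = 10.0
    mesh_resolution: float = 14.0  # target edge length, mm
    seed: int = 0

    def __post_init__(self) -> None:
        pos = [
            self.shaft_length,
            self.shaft_radii[0],
            self.shaft_radii[1],
            self.head_radius,
            self.epicondyle_half_span,
            self.cartilage_cap_thickness,
            self.mesh_resolution,
        ]
        if any(v <= 0 for v in pos):
            raise ValueError(f"all lengths must be strictly positive, got {self}")
        if self.dorsal_process_height < 0:
            raise ValueError("dorsal_process_height must be >= 0")
        if not (0.0 <= self.dorsal_process_position <= 1.0):
            raise ValueError("dorsal_process_position must lie in [0, 1]")
        if self.cartilage_cap_thickness > self.head_radius:
            raise ValueError("cartilage cap thicker than the head radius")


@dataclass
class SyntheticCase:
    """A complete synthetic analysis case with optional ground truth."""

    mesh: TetMesh
    muscles: list
    poses: tuple  # (downstroke, neutral, upstroke) FlipperPose
    known_forces: dict | None = None  # muscle name -> N
    params: BoneParams | None = None


def structured_box(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int) -> TetMesh:
    """Axis-aligned box meshed by 6-tet hex splitting (a test workhorse)."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    grid_x, grid_y, grid_z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([grid_x, grid_y, grid_z], -1).reshape(-1, 3)
    tets = _hexes_to_tets(nx, ny, nz, lambda i, j, k: (i * (ny + 1) + j) * (nz + 1) + k)
    mesh = TetMesh(nodes, tets)
    mesh.fix_orientation()
    return mesh


def _hexes_to_tets(nx: int, ny: int, nz: int, nid) -> np.ndarray:
    corners = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                n000, n100, n010, n110, n001, n101, n011, n111 = (
                    nid(i + a, j + b, k + c) for a, b, c in corners
                )
                tets.extend(
                    [
                        (n000, n100, n110, n111),
                        (n000, n110, n010, n111),
                        (n000, n010, n011, n111),
                        (n000, n011, n001, n111),
                        (n000, n001, n101, n111),
                        (n000, n101, n100, n111),
                    ]
                )
    return np.array(tets, dtype=np.int64)


def _cross_section_template(c: int, nr: int, s: float = 0.45):
    """O-grid template of the unit disk: a square core of (2c)^2 cells
    plus ``nr`` transition rings out to the unit circle.

    Returns (points (n,2), quads (m,4) CCW, outer_ring_ids, angles of the
    outer-ring points).  The O-grid avoids the degenerate cells that
    tensor-product square-to-disk maps produce at the square corners.
    """
    n_side = 2 * c + 1
    us = np.linspace(-s, s, n_side)
    core_pts = np.array([[u, v] for u in us for v in us])

    def cid(i, j):
        return i * n_side + j

    quads = [
        (cid(i, j), cid(i + 1, j), cid(i + 1, j + 1), cid(i, j + 1))
        for i in range(2 * c)
        for j in range(2 * c)
    ]
    # core perimeter ordered counterclockwise by angle
    per = [
        (i, j)
        for i in range(n_side)
        for j in range(n_side)
        if i in (0, n_side - 1) or j in (0, n_side - 1)
    ]
    per_ids = [cid(i, j) for i, j in per]
    ang = np.arctan2(core_pts[per_ids, 1], core_pts[per_ids, 0])
    order = np.argsort(ang)
    boundary = [per_ids[k] for k in order]
    n_b = len(boundary)

    pts = [core_pts]
    n_core = len(core_pts)
    ring_ids = []
    prev = boundary
    # outer-circle targets at uniform angles (aligned with the perimeter
    # ordering) keep the transition cells from degenerating into kites
    theta0 = float(np.arctan2(core_pts[boundary[0], 1], core_pts[boundary[0], 0]))
    target = theta0 + 2.0 * np.pi * np.arange(n_b) / n_b
    circ = np.column_stack([np.cos(target), np.sin(target)])
    for layer in range(1, nr + 1):
        t = layer / nr
        b_pts = core_pts[boundary]
        layer_pts = b_pts + t * (circ - b_pts)
        base = n_core + (layer - 1) * n_b
        ids = list(range(base, base + n_b))
        pts.append(layer_pts)
        for k in range(n_b):
            k1 = (k + 1) % n_b
            quads.append((prev[k], prev[k1], ids[k1], ids[k]))
        ring_ids.append(ids)
        prev = ids
    points = np.vstack(pts)
    outer = np.array(ring_ids[-1])
    outer_ang = np.arctan2(points[outer, 1], points[outer, 0])
    return points, np.array(quads, dtype=np.int64), outer, outer_ang


def _hexes_to_tets_centroid(hexes: np.ndarray, nodes: np.ndarray):
    """Split hexes (8 ids: bottom quad CCW, then top quad) into 12 tets
    each via face triangles + the hex centroid.  Face quads are split
    along the diagonal through their smallest global node id, so shared
    faces of neighbouring hexes triangulate identically (conforming)."""
    centroids = nodes[hexes].mean(axis=1)
    c0 = len(nodes)
    all_nodes = np.vstack([nodes, centroids])
    faces_local = [
        (0, 3, 2, 1),  # bottom
        (4, 5, 6, 7),  # top
        (0, 1, 5, 4),
        (1, 2, 6, 5),
        (2, 3, 7, 6),
        (3, 0, 4, 7),
    ]
    tets = []
    for h_idx, h in enumerate(hexes):
        cn = c0 + h_idx
        for f in faces_local:
            q = [int(h[k]) for k in f]
            m = int(np.argmin(q))
            p0, p1, p2, p3 = q[m:] + q[:m]
            tets.append((p0, p1, p2, cn))
            tets.append((p0, p2, p3, cn))
    return all_nodes, np.array(tets, dtype=np.int64)


def generate_bone(params: BoneParams) -> TetMesh:
    """Build the synthetic bone + bonded cartilage cap as a tet4 mesh.

    Named surface sets: ``proximal_cartilage_top`` (the fixed boundary),
    ``distal_articular``, ``dorsal_process``, ``anterior_epicondyle``,
    ``posterior_epicondyle``.  Deterministic: identical params give
    byte-identical arrays.
    """
    length = params.shaft_length
    cap = params.cartilage_cap_thickness
    r_a, r_b = params.shaft_radii
    h = params.mesh_resolution

    n_cap = max(1, int(round(cap / h)))
    max_r = max(r_a, r_b, params.head_radius, params.epicondyle_half_span)
    min_r = min(r_a, r_b)
    # balance angular, radial and axial cell sizes: the thin direction of
    # any cell must not fall far below the target edge length, otherwise
    # the 12-tet split degrades (radius-ratio floor of 0.05)
    c = max(3, min(5, int(round(_C_FACTOR * np.pi * min_r / h))))
    pole_arc = 2.0 * np.pi * min_r / (8 * c)
    dx = min(h, _DX_FACTOR * pole_arc)
    n_len = max(6, int(np.ceil(length / dx)))
    nr = max(2, int(round(0.45 * max_r / h)))
    pts2d, quads, outer_ids, outer_ang = _cross_section_template(c, nr)
    n_hex = (n_cap + n_len) * len(quads)
    n_el = 12 * n_hex
    if not (200 <= n_el <= 200_000):
        raise ValueError(
            f"mesh_resolution {h} mm yields {n_el} elements "
            "(allowed range: 200 to 200000); adjust the resolution"
        )

    xs = np.concatenate(
        [np.linspace(-cap, 0.0, n_cap + 1)[:-1], np.linspace(0.0, length, n_len + 1)]
    )
    x_pr = params.dorsal_process_position * length
    lam_head = 0.9 * params.head_radius
    lam_epi = max(_LAM_EPI_FACTOR * params.epicondyle_half_span, 1e-9)
    lam_pr = max(2.0 * params.dorsal_process_height, 1e-9)

    def radii(x):
        """Anterior (y) and dorsal (z) semi-axes along the shaft."""
        xe = np.maximum(x, 0.0)  # cap follows the head section at x=0
        g_head = np.exp(-((xe / lam_head) ** 2))
        g_epi = np.exp(-(((xe - length) / lam_epi) ** 2))
        a = r_a + (params.head_radius - r_a) * g_head + (params.epicondyle_half_span - r_a) * g_epi
        b = r_b + (params.head_radius - r_b) * g_head
        return a, b

    n_c = len(pts2d)
    p, q = pts2d[:, 0], pts2d[:, 1]
    layers = []
    for x in xs:
        a, b = radii(x)
        y = a * p
        z = b * q + (
            params.dorsal_process_height
            * np.exp(-(((x - x_pr) / lam_pr) ** 2))
            * np.exp(-((p / 0.6) ** 2))
            * np.clip(q, 0.0, 1.0) ** 2
        )
        layers.append(np.column_stack([np.full(n_c, x), y, z]))
    grid_nodes = np.vstack(layers)

    hexes = []
    for i in range(len(xs) - 1):
        base0, base1 = i * n_c, (i + 1) * n_c
        for quad in quads:
            hexes.append(
                [base0 + quad[0], base0 + quad[1], base0 + quad[2], base0 + quad[3],
                 base1 + quad[0], base1 + quad[1], base1 + quad[2], base1 + quad[3]]
            )
    nodes, tets = _hexes_to_tets_centroid(np.array(hexes, dtype=np.int64), grid_nodes)
    region = np.where(nodes[tets, 0].mean(axis=1) < 0.0, "cartilage", "bone").astype(object)
    mesh = TetMesh(nodes, tets, region)
    mesh.fix_orientation()

    sets = {
        "proximal_cartilage_top": np.arange(n_c),
        "distal_articular": np.arange((len(xs) - 1) * n_c, len(xs) * n_c),
    }
    deg = np.degrees(outer_ang)
    station = {
        name: [i for i, x in enumerate(xs) if cond(x)]
        for name, cond in {
            "process": lambda x: abs(x - x_pr) <= max(lam_pr, 1.5 * h),
            "distal": lambda x: length - 1.5 * lam_epi <= x <= length,
        }.items()
    }

    def rim_nodes(stations, ang_mask):
        ids = []
        sel = outer_ids[ang_mask]
        for i in stations:
            ids.extend((i * n_c + sel).tolist())
        return np.array(sorted(set(ids)), dtype=np.int64)

    sets["dorsal_process"] = rim_nodes(station["process"], np.abs(deg - 90.0) <= 40.0)
    sets["anterior_epicondyle"] = rim_nodes(station["distal"], np.abs(deg) <= 35.0)
    sets["posterior_epicondyle"] = rim_nodes(station["distal"], np.abs(np.abs(deg) - 180.0) <= 35.0)
    mesh.node_sets = {k: np.sort(np.unique(v)).astype(np.int64) for k, v in sets.items()}
    mesh.__post_init__()  # re-validate sets
    return mesh


# ---------------------------------------------------------------------- #
# muscle apparatus


def _geodesic_disk(mesh: TetMesh, center_node: int, radius: float) -> np.ndarray:
    """Surface nodes within geodesic distance ``radius`` of a seed node,
    measured along the boundary-triangle edge graph."""
    tris, _ = mesh.surface()
    edges = np.unique(np.sort(tris[:, [0, 1, 1, 2, 0, 2]].reshape(-1, 2), axis=1), axis=0)
    w = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1)
    n = mesh.n_nodes
    g = sp.coo_matrix((np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n)).tocsr()
    dist = dijkstra(g, indices=center_node, directed=False, limit=radius * 1.001)
    out = np.where(np.isfinite(dist) & (dist <= radius))[0]
    return out.astype(np.int64)


def _nearest_surface_node(mesh: TetMesh, point: np.ndarray, candidates: np.ndarray | None = None) -> int:
    if candidates is None:
        candidates = np.unique(mesh.surface()[0])
    d = np.linalg.norm(mesh.nodes[candidates] - np.asarray(point), axis=1)
    return int(candidates[int(np.argmin(d))])


def generate_muscle_set(
    mesh: TetMesh,
    n_per_role: int = 2,
    seed: int = 0,
    attachment_radius: float = 18.0,
) -> list:
    """Deterministic muscle apparatus for a synthetic bone.

    Creates ``n_per_role`` muscles for each of the seven functional roles,
    arranged so the tension chords hug the bone the way flipper muscles
    do.  Girdle muscles (depressors, elevators, pro-/retractors) wrap the
    proximal head rim — elevators over the dorsal process apex — and run
    to origins tucked close behind the joint, so each chord squeezes the
    shaft segment between its via contact and its staggered insertion.
    Extensors and flexors attach on the distal shaft, wrap the
    anterior/posterior epicondyle, and pull distally toward off-bone
    origins standing in for the rest of the flipper.  Attachment node
    sets are geodesic disks registered on the mesh as ``ins_<name>``.
    """
    if n_per_role < 1:
        raise ValueError(
            "n_per_role must be >= 1: every antagonistic pair needs both members, "
            "otherwise the load case is unconstrained"
        )
    for required in ("dorsal_process", "anterior_epicondyle", "posterior_epicondyle", "distal_articular"):
        if required not in mesh.node_sets:
            raise ValueError(f"mesh lacks required named set {required!r}")
    rng = np.random.default_rng(seed)
    surf = np.unique(mesh.surface()[0])
    pts = mesh.nodes
    length = pts[mesh.node_sets["distal_articular"], 0].mean()
    cap = -pts[:, 0].min()  # cartilage cap thickness
    y_max = pts[surf, 1].max()
    z_max = pts[surf, 2].max()
    z_min = pts[surf, 2].min()
    y_min = pts[surf, 1].min()

    # apex via-points of the named processes
    dp = mesh.node_sets["dorsal_process"]
    dp_apex = pts[dp[np.argmax(pts[dp, 2])]]
    ae = mesh.node_sets["anterior_epicondyle"]
    ae_apex = pts[ae[np.argmax(pts[ae, 1])]]
    pe = mesh.node_sets["posterior_epicondyle"]
    pe_apex = pts[pe[np.argmin(pts[pe, 1])]]

    x_rim = 0.05 * length  # head-rim via station for girdle chords
    origin_x = -(cap + 8.0)  # just behind the cartilage cap, off the mesh

    def rim_point(direction):
        """Point on the head rim in a transverse direction (unit 2-vector
        in the (y, z) plane)."""
        target = np.array([x_rim, direction[0] * 1.5 * y_max, direction[1] * 1.5 * z_max])
        return pts[_nearest_surface_node(mesh, target, surf)]

    muscles = []

    def jit(scale=6.0):
        return rng.uniform(-scale, scale)

    def attach(name, target_point):
        seed_node = _nearest_surface_node(mesh, target_point, surf)
        disk = _geodesic_disk(mesh, seed_node, attachment_radius)
        set_name = f"ins_{name}"
        mesh.node_sets[set_name] = disk
        return set_name

    def add(name, role, origin, insertion_point, vias=(), sense=None):
        set_name = attach(name, insertion_point)
        muscles.append(
            MusclePath(
                name=name,
                roles=frozenset({role}),
                origin=np.asarray(origin, dtype=float),
                via_points=[np.asarray(v, dtype=float) for v in vias],
                insertion_set=set_name,
                rotation_sense=sense,
            )
        )

    for i in range(n_per_role):
        t = (i + 0.5) / n_per_role
        x_ins = (0.45 + 0.55 * t) * length + jit(4)  # staggered insertions
        # girdle muscles: via on the head rim, origin hugging the joint so
        # the chord dives steeply and its contact squeezes the shaft
        add(
            f"depressor_{i}",
            "depressor",
            origin=(origin_x + jit(3), 6 * (t - 0.5) + jit(3), 0.25 * z_min),
            insertion_point=(x_ins, 0.0, z_min),
            vias=(rim_point((0.0, -1.0)),),
        )
        add(
            f"elevator_{i}",
            "elevator",
            origin=(origin_x + jit(3), 6 * (t - 0.5) + jit(3), 0.25 * z_max),
            insertion_point=(min(x_ins + 0.05 * length, 0.8 * length), 0.0, z_max),
            vias=(dp_apex,),
        )
        add(
            f"protractor_{i}",
            "protractor",
            origin=(origin_x + jit(3), 0.25 * y_max, 6 * (t - 0.5) + jit(3)),
            insertion_point=(x_ins, y_max, 0.0),
            vias=(rim_point((1.0, 0.0)),),
        )
        add(
            f"retractor_{i}",
            "retractor",
            origin=(origin_x + jit(3), 0.25 * y_min, 6 * (t - 0.5) + jit(3)),
            insertion_point=(x_ins, y_min, 0.0),
            vias=(rim_point((-1.0, 0.0)),),
        )
        sense = "down" if i % 2 == 0 else "up"
        sgn = -1.0 if sense == "down" else 1.0
        # rotators: oblique chords over the head rim producing axial torque
        add(
            f"rotator_{i}",
            "rotator",
            origin=(origin_x + jit(3), sgn * 0.2 * y_max, -sgn * 0.2 * z_max),
            insertion_point=(0.5 * length + jit(4), sgn * 0.8 * y_max, sgn * 0.7 * z_max),
            vias=(rim_point((sgn * 0.7, sgn * 0.7)),),
            sense=sense,
        )
        # distal-limb muscles: attach on the distal shaft, wrap the
        # epicondyle apex, pull distally toward the rest of the flipper
        add(
            f"extensor_{i}",
            "extensor",
            origin=(length + 30.0 + jit(), 0.2 * ae_apex[1] + jit(3), 10.0 + jit(3)),
            insertion_point=(0.80 * length - 6 * i, 0.9 * y_max, 0.2 * z_max),
            vias=(ae_apex,),
        )
        add(
            f"flexor_{i}",
            "flexor",
            origin=(length + 30.0 + jit(), 0.2 * pe_apex[1] + jit(3), -10.0 + jit(3)),
            insertion_point=(0.80 * length - 6 * i, 0.9 * y_min, -0.2 * z_max),
            vias=(pe_apex,),
        )
    return muscles


def default_poses() -> tuple:
    """Downstroke / neutral / upstroke poses for the length-change analysis:
    +/-50 deg elevation; the FE load cases use the +/-19 deg axial twist."""
    return (
        FlipperPose(elevation_deg=-50.0, twist_deg=-19.0, label="downstroke"),
        FlipperPose(elevation_deg=0.0, twist_deg=0.0, label="neutral"),
        FlipperPose(elevation_deg=50.0, twist_deg=19.0, label="upstroke"),
    )


def sample_known_forces(muscles: list, seed: int = 0) -> dict:
    """Ground-truth forces, log-uniform in [100, 10000] N per antagonistic
    pair (both members of a pair receive the pair's draw, so the synthetic
    loading is balanced enough to stay within the compressive bands)."""
    rng = np.random.default_rng(seed)
    by_role = {}
    for m in muscles:
        role = next(iter(m.roles))
        by_role.setdefault(role, []).append(m)
    forces = {}
    n = max(len(v) for v in by_role.values())
    for i in range(n):
        for a_role, b_role in ROLE_PAIRS:
            f = float(np.exp(rng.uniform(np.log(100.0), np.log(10_000.0))))
            for role in (a_role, b_role):
                lst = by_role.get(role, [])
                if i < len(lst):
                    forces[lst[i].name] = f
    rotators = by_role.get("rotator", [])
    for i in range(0, len(rotators), 2):
        f = float(np.exp(rng.uniform(np.log(100.0), np.log(10_000.0))))
        for m in rotators[i : i + 2]:
            forces[m.name] = f
    return forces


def generate_case(
    params: BoneParams | None = None,
    n_per_role: int = 2,
    seed: int = 0,
    with_known_forces: bool = True,
) -> SyntheticCase:
    """One-stop synthetic case: bone, muscles, poses, optional ground truth."""
    params = replace(params, seed=seed) if params is not None else BoneParams(seed=seed)
    mesh = generate_bone(params)
    muscles = generate_muscle_set(mesh, n_per_role=n_per_role, seed=seed)
    known = sample_known_forces(muscles, seed=seed + 1) if with_known_forces else None
    return SyntheticCase(mesh=mesh, muscles=muscles, poses=default_poses(), known_forces=known, params=params)
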