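"""Small-displacement linear-elastic finite-element core for tet meshes.

The solver supports 4-node (constant-strain) and 10-node (quadratic)
tetrahedra, the latter matching the topology of the classic SOLID92
element: straight edges with midside nodes, four-point Gauss quadrature.
Stress is recovered per element — the constant value for linear tets, the
integration-point average for quadratic tets — and reported as the full
Cauchy tensor plus sorted principal values and the maximum shear
tau = (sigma1 - sigma3)/2.

All quantities are in the mm/N/MPa unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Material, TetMesh, quadratic_edge_map, tet_volumes, write_vtu

__all__ = [
    "BoundaryCondition",
    "StressField",
    "StiffnessOperator",
    "assemble",
    "solve_static",
    "principal",
    "traction_loads",
    "elasticity_matrix",
]

# 4-point Gauss rule for the reference tetrahedron (degree-2 exact),
# barycentric points; weights sum to 1 and are scaled by the tet volume.
_GA, _GB = 0.5854101966249685, 0.1381966011250105
_GAUSS_TET4PT = np.array(
    [
        [_GA, _GB, _GB, _GB],
        [_GB, _GA, _GB, _GB],
        [_GB, _GB, _GA, _GB],
        [_GB, _GB, _GB, _GA],
    ]
)


def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic elasticity matrix, Voigt order (xx,yy,zz,xy,yz,xz)
    with engineering shear strains."""
    e, nu = material.young_modulus, material.poisson_ratio
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] += 2 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


@dataclass
class BoundaryCondition:
    """Dirichlet constraints plus nodal point loads.

    ``fixed_nodes`` pins all three components; ``fixed_components`` pins
    individual (node, component) pairs (component in 0..2).  Loads are a
    list of (node, 3-vector N) pairs or a dense (N,3) array.
    """

    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    fixed_components: list = field(default_factory=list)
    loads: object = None  # list[(node, vec)] | (N,3) array | None

    def fixed_dofs(self, n_nodes: int) -> np.ndarray:
        dofs = set()
        for n in np.asarray(self.fixed_nodes, dtype=np.int64):
            dofs.update((3 * int(n), 3 * int(n) + 1, 3 * int(n) + 2))
        for n, c in self.fixed_components:
            dofs.add(3 * int(n) + int(c))
        return np.array(sorted(dofs), dtype=np.int64)

    def load_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(3 * n_nodes)
        if self.loads is None:
            return f
        if isinstance(self.loads, np.ndarray) and self.loads.shape == (n_nodes, 3):
            return self.loads.reshape(-1).astype(float)
        for n, vec in self.loads:
            f[3 * int(n) : 3 * int(n) + 3] += np.asarray(vec, dtype=float)
        return f


@dataclass
class StressField:
    """Solution container: per-element stress and per-node displacement."""

    tensor: np.ndarray  # (M, 3, 3) Cauchy stress, MPa
    sigma1: np.ndarray  # (M,) most tensile principal stress
    sigma2: np.ndarray
    sigma3: np.ndarray  # (M,) most compressive principal stress
    tau: np.ndarray  # (M,) max shear (sigma1 - sigma3)/2
    displacement: np.ndarray  # (N, 3) mm
    reactions: np.ndarray  # (N, 3) nodal reaction forces at fixed dofs
    mesh: TetMesh = None

    @property
    def voigt(self) -> np.ndarray:
        t = self.tensor
        return np.stack(
            [t[:, 0, 0], t[:, 1, 1], t[:, 2, 2], t[:, 0, 1], t[:, 1, 2], t[:, 0, 2]],
            axis=1,
        )

    def to_vtu(self, path) -> None:
        """Export for ParaView-style inspection (cell sigma1/sigma3/tau,
        point displacement)."""
        write_vtu(
            self.mesh,
            path,
            cell_data={"sigma1": self.sigma1, "sigma3": self.sigma3, "tau": self.tau},
            point_data={"displacement": self.displacement},
        )

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sigma1_mpa": self.sigma1,
                "sigma3_mpa": self.sigma3,
                "tau_mpa": self.tau,
                "region": self.mesh.region if self.mesh is not None else "",
            }
        )


class StiffnessOperator:
    """Assembled global stiffness with cached element data for stress
    recovery.  Behaves as a symmetric positive-semidefinite sparse matrix."""

    def __init__(self, mesh: TetMesh, k: sp.csr_matrix, b_mean: np.ndarray, d_per_el: np.ndarray):
        self.mesh = mesh
        self.matrix = k
        self._b_mean = b_mean  # (M, 6, ndof_el) mean strain-displacement
        self._d = d_per_el  # (M, 6, 6)

    @property
    def shape(self):
        return self.matrix.shape

    def element_stress(self, u: np.ndarray) -> np.ndarray:
        """Per-element Voigt stress for a global displacement vector."""
        el = self.mesh.elements
        dof = (3 * el[:, :, None] + np.arange(3)).reshape(len(el), -1)
        ue = u[dof]  # (M, ndof_el)
        strain = np.einsum("mij,mj->mi", self._b_mean, ue)
        return np.einsum("mij,mj->mi", self._d, strain)


def _tet10_shape_gradients():
    """Gradients of the 10 shape functions w.r.t. (xi, eta, zeta) at the
    4 Gauss points; returns (4, 10, 3)."""
    # barycentric L = (L0, L1, L2, L3), with d(L)/d(xi,eta,zeta) constant:
    dl = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])  # (4,3)
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    out = np.zeros((4, 10, 3))
    for g, l in enumerate(_GAUSS_TET4PT):
        for c in range(4):  # corner nodes: N = L(2L-1)
            out[g, c] = (4 * l[c] - 1) * dl[c]
        for k, (a, b) in enumerate(edges):  # midside: N = 4 La Lb
            out[g, 4 + k] = 4 * (l[a] * dl[b] + l[b] * dl[a])
    return out


_TET10_DNDXI = _tet10_shape_gradients()
# linear tet: N = L, gradient constant
_TET4_DNDXI = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def _b_from_grad(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from shape-function gradients.

    grad: (..., n_nodes, 3) cartesian gradients -> (..., 6, 3*n_nodes)
    """
    shp = grad.shape[:-2]
    n = grad.shape[-2]
    b = np.zeros(shp + (6, 3 * n))
    gx, gy, gz = grad[..., 0], grad[..., 1], grad[..., 2]
    idx = np.arange(n)
    b[..., 0, 3 * idx + 0] = gx
    b[..., 1, 3 * idx + 1] = gy
    b[..., 2, 3 * idx + 2] = gz
    b[..., 3, 3 * idx + 0] = gy
    b[..., 3, 3 * idx + 1] = gx
    b[..., 4, 3 * idx + 1] = gz
    b[..., 4, 3 * idx + 2] = gy
    b[..., 5, 3 * idx + 0] = gz
    b[..., 5, 3 * idx + 2] = gx
    return b


def assemble(mesh: TetMesh, materials: dict) -> StiffnessOperator:
    """Assemble the global stiffness matrix.

    ``materials`` maps region name -> Material; every region present in the
    mesh must be covered.  Raises on inverted (non-positive volume)
    elements, naming the first offender.
    """
    regions = set(mesh.region.tolist())
    missing = regions - set(materials)
    if missing:
        raise ValueError(f"no material for region(s): {sorted(missing)}")

    corners = mesh.corners
    p = mesh.nodes[corners]
    jac = p[:, 1:] - p[:, :1]  # (M,3,3): rows d(x)/d(xi_i) for linear map
    detj = np.linalg.det(jac)
    bad = np.where(detj <= 0)[0]
    if bad.size:
        raise ValueError(
            f"inverted element {int(bad[0])} (volume {detj[bad[0]] / 6.0:.3g} mm^3); "
            "run TetMesh.fix_orientation() first"
        )
    jinv = np.linalg.inv(jac)  # (M,3,3)
    vol = detj / 6.0

    d_stack = np.empty((mesh.n_elements, 6, 6))
    for r in regions:
        d_stack[mesh.region == r] = elasticity_matrix(materials[r])

    if mesh.is_quadratic:
        # cartesian gradients at each Gauss point: dN/dx = dN/dxi . jinv
        grad = np.einsum("gnk,mjk->gmnj", _TET10_DNDXI, jinv)  # (4,M,10,3)
        b = _b_from_grad(grad)  # (4, M, 6, 30)
        w = (vol / 4.0)[:, None, None]  # equal weights
        ke = np.zeros((mesh.n_elements, 30, 30))
        for g in range(4):
            bg = b[g]
            ke += np.matmul(bg.transpose(0, 2, 1), np.matmul(d_stack, bg)) * w
        b_mean = b.mean(axis=0)
    else:
        grad = np.einsum("nk,mjk->mnj", _TET4_DNDXI, jinv)  # (M,4,3)
        b = _b_from_grad(grad)  # (M, 6, 12)
        ke = np.matmul(b.transpose(0, 2, 1), np.matmul(d_stack, b)) * vol[:, None, None]
        b_mean = b

    el = mesh.elements
    dof = (3 * el[:, :, None] + np.arange(3)).reshape(len(el), -1)  # (M, ndof)
    nd = dof.shape[1]
    rows = np.repeat(dof, nd, axis=1).reshape(-1)
    cols = np.tile(dof, (1, nd)).reshape(-1)
    k = sp.coo_matrix(
        (ke.reshape(-1), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    ).tocsr()
    k = 0.5 * (k + k.T)  # enforce exact symmetry
    return StiffnessOperator(mesh, k, b_mean, d_stack)


def _recover(op: StiffnessOperator, u: np.ndarray, reactions: np.ndarray) -> StressField:
    voigt = op.element_stress(u)
    t = np.zeros((len(voigt), 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = voigt[:, 0], voigt[:, 1], voigt[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = voigt[:, 3]
    t[:, 1, 2] = t[:, 2, 1] = voigt[:, 4]
    t[:, 0, 2] = t[:, 2, 0] = voigt[:, 5]
    s1, s2, s3, tau = principal(t)
    return StressField(
        tensor=t,
        sigma1=s1,
        sigma2=s2,
        sigma3=s3,
        tau=tau,
        displacement=u.reshape(-1, 3),
        reactions=reactions.reshape(-1, 3),
        mesh=op.mesh,
    )


def make_solver(op: StiffnessOperator, bc: BoundaryCondition):
    """Factorize the constrained system once; return f_global -> u_global.

    Used directly by the muscle-force optimizer, where many load vectors
    are solved against one set of boundary conditions.
    """
    n = op.mesh.n_nodes
    fixed = bc.fixed_dofs(n)
    if fixed.size == 0:
        raise ValueError(
            "no fixed boundary: the static problem is singular; "
            "constrain at least the proximal cartilage surface"
        )
    free = np.setdiff1d(np.arange(3 * n), fixed)
    kff = op.matrix[np.ix_(free, free)].tocsc()
    # symmetric-friendly fill-reducing ordering
    lu = spla.splu(kff, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})

    def solve(f: np.ndarray) -> np.ndarray:
        u = np.zeros(3 * n)
        u[free] = lu.solve(f[free])
        return u

    return solve, free, fixed


def solve_static(op: StiffnessOperator, bc: BoundaryCondition) -> StressField:
    """Solve K u = f with Dirichlet constraints; recover element stresses.

    Verifies the relative residual on the free dofs (< 1e-8) and reports
    reactions at the fixed dofs.
    """
    solve, free, fixed = make_solver(op, bc)
    f = bc.load_vector(op.mesh.n_nodes)
    u = solve(f)
    # residual check on free dofs
    r = op.matrix @ u - f
    denom = max(np.linalg.norm(f[free]), 1e-30)
    rel = np.linalg.norm(r[free]) / denom
    if np.linalg.norm(f[free]) > 0 and rel > 1e-8:
        raise RuntimeError(f"solver residual too large: {rel:.3e}")
    reactions = np.zeros_like(u)
    reactions[fixed] = r[fixed]
    return _recover(op, u, reactions)


def principal(tensor: np.ndarray):
    """Sorted principal stresses and max shear of symmetric 3x3 tensor(s).

    Returns (sigma1, sigma2, sigma3, tau) with sigma1 >= sigma2 >= sigma3
    and tau = (sigma1 - sigma3) / 2.  Raises on non-symmetric input.
    """
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    scale = np.abs(t).max(axis=(1, 2))
    asym = np.abs(t - np.swapaxes(t, 1, 2)).max(axis=(1, 2))
    if np.any(asym > 1e-9 * np.maximum(scale, 1.0)):
        raise ValueError("stress tensor is not symmetric")
    vals = np.linalg.eigvalsh(0.5 * (t + np.swapaxes(t, 1, 2)))  # ascending
    s1, s2, s3 = vals[:, 2], vals[:, 1], vals[:, 0]
    tau = 0.5 * (s1 - s3)
    if single:
        return s1[0], s2[0], s3[0], tau[0]
    return s1, s2, s3, tau


def traction_loads(mesh: TetMesh, node_set: str, traction: np.ndarray) -> list:
    """Consistent nodal loads for a uniform traction (MPa) on the boundary
    triangles whose corner nodes all belong to ``node_set``.

    For linear faces each corner carries t*A/3; for quadratic faces the
    corner loads vanish and each midside node carries t*A/3 — the
    consistent load vector of a straight-sided quadratic triangle.
    """
    traction = np.asarray(traction, dtype=float)
    sel = set(np.asarray(mesh.node_sets[node_set]).tolist())
    tris, _ = mesh.surface()
    emap = quadratic_edge_map(mesh) if mesh.is_quadratic else None
    loads = {}

    def add(n, v):
        loads[n] = loads.get(n, np.zeros(3)) + v

    for tri in tris:
        if not all(int(v) in sel for v in tri):
            continue
        p = mesh.nodes[tri]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        share = traction * (area / 3.0)
        if emap is None:
            for v in tri:
                add(int(v), share)
        else:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])):
                m = emap[(min(int(a), int(b)), max(int(a), int(b)))]
                add(m, share)
    return [(n, v) for n, v in sorted(loads.items())]
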