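"""Shared fixtures: small analytic meshes and the (expensive) synthetic
bone case with its optimized load cases, built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from flipperfea import DEFAULT_MATERIALS
from flipperfea.loads import FlipperPose, LoadCase, MusclePath
from flipperfea.mesh import Material, TetMesh, to_quadratic
from flipperfea.optimize import OptimizationConfig, build_case_system, optimize
from flipperfea.synthetic import generate_case, structured_box

BONE = {"bone": Material(12_000.0, 0.3)}


@pytest.fixture(scope="session")
def materials():
    return DEFAULT_MATERIALS


def make_bar(nx=10, ny=2, nz=2, lx=100.0, ly=10.0, lz=10.0, quadratic=False) -> TetMesh:
    """Bar along +x with named end-face node sets (after any quadratic
    conversion, so midside nodes are included)."""
    mesh = structured_box(lx, ly, lz, nx, ny, nz)
    if quadratic:
        mesh = to_quadratic(mesh)
    mesh.node_sets["x0_face"] = np.where(np.isclose(mesh.nodes[:, 0], 0.0))[0]
    mesh.node_sets["x1_face"] = np.where(np.isclose(mesh.nodes[:, 0], lx))[0]
    return mesh


def compression_bar_system(force_bounds=(1.0, 20_000.0), seed=0, iterations=40):
    """One-muscle bar: a chord threaded through the bar pulls the free
    face toward a far distal origin, compressing the bar against the
    fixed face (sigma3 = -F/A with A = 100 mm^2).  The counterforce set
    coincides with the fixed face, where it is absorbed by the supports.
    """
    mesh = make_bar()
    mesh.node_sets["proximal_cartilage_top"] = mesh.node_sets["x1_face"]
    mesh.node_sets["distal_articular"] = mesh.node_sets["x1_face"]
    mesh.node_sets["ins_axial"] = mesh.node_sets["x0_face"]
    muscle = MusclePath(
        name="axial",
        roles=frozenset({"depressor"}),
        origin=np.array([1000.0, 5.0, 5.0]),
        insertion_set="ins_axial",
    )
    passive = MusclePath(
        name="opposer",
        roles=frozenset({"elevator"}),
        origin=np.array([1000.0, 5.0, 5.0]),
        insertion_set="ins_axial",
    )
    case = LoadCase(pose=FlipperPose(0.0, 0.0, "neutral"), muscles=[muscle, passive])
    cfg = OptimizationConfig(
        force_bounds=force_bounds, seed=seed, iterations=iterations, n_monitor=6
    )
    system = build_case_system(mesh, case, BONE, config=cfg)
    return system, cfg


@pytest.fixture(scope="session")
def bone_case():
    return generate_case(seed=0)


@pytest.fixture(scope="session")
def down_system(bone_case):
    case = LoadCase(
        pose=FlipperPose(0.0, -19.0, "downstroke"), muscles=bone_case.muscles
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_case_system(bone_case.mesh, case, DEFAULT_MATERIALS)


@pytest.fixture(scope="session")
def up_system(bone_case):
    case = LoadCase(
        pose=FlipperPose(0.0, 19.0, "upstroke"), muscles=bone_case.muscles
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_case_system(bone_case.mesh, case, DEFAULT_MATERIALS)


@pytest.fixture(scope="session")
def down_solution(down_system):
    return optimize(down_system, OptimizationConfig(seed=1))


@pytest.fixture(scope="session")
def up_solution(up_system):
    return optimize(up_system, OptimizationConfig(seed=1))


@pytest.fixture(scope="session")
def cantilever_result():
    """Quadratic-tet cantilever, tip-loaded: fixed at x=0, uniform shear
    traction on the free end.  Returns (tip deflection mm, beam theory
    prediction mm, operator, solution)."""
    from flipperfea.fe import BoundaryCondition, solve_static, traction_loads

    lx, w, h = 100.0, 10.0, 10.0
    force = 100.0
    mesh = make_bar(nx=50, ny=5, nz=5, lx=lx, ly=w, lz=h, quadratic=True)
    from flipperfea.fe import assemble

    op = assemble(mesh, BONE)
    bc = BoundaryCondition(
        fixed_nodes=mesh.node_sets["x0_face"],
        loads=traction_loads(mesh, "x1_face", np.array([0.0, 0.0, force / (w * h)])),
    )
    sol = solve_static(op, bc)
    tip = sol.displacement[mesh.node_sets["x1_face"], 2].mean()
    euler = 4 * force * lx**3 / (12_000.0 * w * h**3)
    return tip, euler, op, sol
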