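"""Muscle definitions and their conversion into FE nodal load sets.

A muscle is modelled as a tension chord: a polyline line of action (LOA)
from its on-bone attachment through optional via-points (wrapping) to an
off-bone origin.  Under tension F the chord loads the bone three ways:

* a distributed pull over the attachment node set, along the first LOA
  segment (optionally split into weighted subsections);
* a frictionless-post contact force F*(u_prev + u_next) at every
  via-point, pressing into the surface — this is how wrapping muscles
  compress processes such as the dorsal tuberosity and the epicondyles;
* its share of the equilibrating counterforce applied over the distal
  articular surface, which stands in for the rest of the flipper.

The counterforce enforces translational equilibrium only; the residual
moment is reported per load case rather than cancelled, mirroring the
procedure of applying a force resultant on the distal joint surface.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import TetMesh

__all__ = [
    "MusclePath",
    "FlipperPose",
    "LoadCase",
    "line_of_action",
    "distribute_attachment_load",
    "wrapping_loads",
    "counterforce",
    "build_case_loads",
    "pose_rotation",
    "write_muscle_csv",
    "read_muscle_csv",
    "DOWNSTROKE_AGONIST_ROLES",
    "UPSTROKE_AGONIST_ROLES",
]

DOWNSTROKE_AGONIST_ROLES = frozenset({"depressor", "retractor", "flexor"})
UPSTROKE_AGONIST_ROLES = frozenset({"elevator", "protractor", "extensor"})


@dataclass
class MusclePath:
    """A named tension chord.

    ``via_points`` are ordered origin -> insertion, on (or near) named
    surface features; ``subsections`` is a list of (weight, direction or
    None) splitting the total force over the attachment, weights summing
    to 1.  ``force`` is assigned by the optimizer (N, >= 0).
    """

    name: str
    roles: frozenset
    origin: np.ndarray
    insertion_set: str
    via_points: list = field(default_factory=list)
    subsections: list = field(default_factory=lambda: [(1.0, None)])
    force: float = 0.0
    two_joint: bool = False
    rotation_sense: str | None = None  # for rotators: "down" | "up"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.via_points = [np.asarray(v, dtype=float) for v in self.via_points]
        w = sum(s[0] for s in self.subsections)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"muscle {self.name!r}: subsection weights sum to {w}, not 1")
        if self.force < 0:
            raise ValueError(f"muscle {self.name!r}: force must be >= 0")

    def is_agonist(self, label: str) -> bool:
        agonist = DOWNSTROKE_AGONIST_ROLES if label == "downstroke" else UPSTROKE_AGONIST_ROLES
        if self.roles & agonist:
            return True
        if "rotator" in self.roles and self.rotation_sense is not None:
            return (label == "downstroke") == (self.rotation_sense == "down")
        return False


@dataclass
class FlipperPose:
    """Flipper orientation: elevation about the anteroposterior axis and
    axial twist about the bone long axis (degrees)."""

    elevation_deg: float = 0.0
    twist_deg: float = 0.0
    label: str = "neutral"

    def __post_init__(self) -> None:
        if not (-50.0 - 1e-9 <= self.elevation_deg <= 50.0 + 1e-9):
            raise ValueError("elevation must lie in [-50, +50] degrees")
        if self.label == "downstroke" and self.twist_deg > 0:
            raise ValueError("downstroke twists the anterior edge down (twist <= 0)")
        if self.label == "upstroke" and self.twist_deg < 0:
            raise ValueError("upstroke twists the anterior edge up (twist >= 0)")


@dataclass
class LoadCase:
    """A static FE problem: pose + active muscles + boundary surfaces."""

    pose: FlipperPose
    muscles: list
    fixed_set: str = "proximal_cartilage_top"
    counterforce_set: str = "distal_articular"
    n_counterforce_points: int = 12

    def __post_init__(self) -> None:
        labels = self.pose.label
        has_agonist = any(m.is_agonist(labels) for m in self.muscles)
        has_antagonist = any(not m.is_agonist(labels) for m in self.muscles)
        if not (has_agonist and has_antagonist):
            raise ValueError(
                "a load case needs at least one agonist and one antagonist: "
                "agonists and antagonists jointly keep the bone under compression"
            )


def pose_rotation(pose: FlipperPose, long_axis=(1.0, 0, 0), elevation_axis=(0, 1.0, 0)) -> Rotation:
    """Proper rotation carrying the neutral limb into the posed limb:
    axial twist about the long axis, then elevation."""
    long_axis = np.asarray(long_axis, dtype=float)
    elevation_axis = np.asarray(elevation_axis, dtype=float)
    r_twist = Rotation.from_rotvec(np.deg2rad(pose.twist_deg) * long_axis / np.linalg.norm(long_axis))
    r_elev = Rotation.from_rotvec(
        np.deg2rad(pose.elevation_deg) * elevation_axis / np.linalg.norm(elevation_axis)
    )
    return r_elev * r_twist


def _posed_origin(muscle: MusclePath, pose: FlipperPose | None, joint_center) -> np.ndarray:
    """Origin coordinates in the bone frame: the bone (and everything tied
    to it) stays fixed while the girdle-side origin is carried by the
    inverse pose rotation about the joint center."""
    if pose is None or (pose.elevation_deg == 0 and pose.twist_deg == 0):
        return muscle.origin
    jc = np.asarray(joint_center, dtype=float)
    rot = pose_rotation(pose)
    return rot.inv().apply(muscle.origin - jc) + jc


def line_of_action(
    muscle: MusclePath,
    mesh: TetMesh,
    pose: FlipperPose | None = None,
    joint_center=(0.0, 0.0, 0.0),
):
    """Polyline of the muscle's LOA from the insertion centroid through the
    via-points to the (posed) origin.

    Returns (points (k,3), unit directions per segment (k-1,3), total
    length).  Raises if any segment has zero length, naming the muscle.
    """
    idx = mesh.node_sets[muscle.insertion_set]
    if len(idx) == 0:
        raise ValueError(f"muscle {muscle.name!r}: empty insertion set")
    start = mesh.nodes[idx].mean(axis=0)
    origin = _posed_origin(muscle, pose, joint_center)
    pts = [start] + list(reversed(muscle.via_points)) + [origin]
    pts = np.asarray(pts, dtype=float)
    seg = np.diff(pts, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths < 1e-12):
        raise ValueError(f"muscle {muscle.name!r}: zero-length LOA segment")
    return pts, seg / lengths[:, None], float(lengths.sum())


def distribute_attachment_load(muscle: MusclePath, mesh: TetMesh, pose: FlipperPose | None = None):
    """Spread the muscle force over its attachment node set.

    Each subsection contributes weight * F along the first LOA segment
    (or its direction override), split equally over the set's nodes; the
    vector sum equals F times the weighted mean direction.
    """
    idx = mesh.node_sets[muscle.insertion_set]
    if len(idx) == 0:
        raise ValueError(f"muscle {muscle.name!r}: empty insertion set")
    _, dirs, _ = line_of_action(muscle, mesh, pose)
    base_dir = dirs[0]
    total = np.zeros(3)
    for weight, override in muscle.subsections:
        d = base_dir if override is None else np.asarray(override, dtype=float)
        d = d / np.linalg.norm(d)
        total = total + weight * d
    per_node = muscle.force * total / len(idx)
    return [(int(n), per_node.copy()) for n in idx]


def wrapping_loads(
    muscle: MusclePath,
    mesh: TetMesh,
    pose: FlipperPose | None = None,
    drop_liftoff: bool = True,
    patch_radius: float = 16.0,
):
    """Frictionless-post contact forces at the via-points.

    At each via-point V between polyline neighbours P and N the chord
    under tension F presses on the bone with F*(unit(P-V) + unit(N-V)).
    The contact is spread over the surface nodes within ``patch_radius``
    of V with a linear taper (a wrap presses over a patch, and a single
    nodal force would create an artificial stress singularity); the
    vector sum is exact.  A via force with positive outward-normal
    component at the contact center (lift-off) is dropped with a warning
    for that pose.
    """
    if not muscle.via_points:
        return []
    pts, _, _ = line_of_action(muscle, mesh, pose)
    normals = mesh.node_normals()
    surf = np.unique(mesh.surface()[0])
    out = []
    for i in range(1, len(pts) - 1):
        v = pts[i]
        u_prev = pts[i - 1] - v
        u_next = pts[i + 1] - v
        force = muscle.force * (
            u_prev / np.linalg.norm(u_prev) + u_next / np.linalg.norm(u_next)
        )
        d = np.linalg.norm(mesh.nodes[surf] - v, axis=1)
        center = int(surf[int(np.argmin(d))])
        n_out = normals.get(center)
        if (
            drop_liftoff
            and n_out is not None
            and np.linalg.norm(force) > 0
            and float(np.dot(force, n_out)) > 1e-9 * max(np.linalg.norm(force), 1.0)
        ):
            warnings.warn(
                f"muscle {muscle.name!r}: via-point {i} lifts off the surface "
                "in this pose; contact dropped",
                stacklevel=2,
            )
            continue
        in_patch = d <= patch_radius
        w = 1.0 - d[in_patch] / max(patch_radius, 1e-12)
        if w.sum() <= 0:
            in_patch = d <= d.min() + 1e-12
            w = np.ones(int(in_patch.sum()))
        w = w / w.sum()
        for node, wk in zip(surf[in_patch], w):
            out.append((int(node), wk * force))
    return out


def counterforce(case: LoadCase, applied: list, mesh: TetMesh, extra_sum=None):
    """Equilibrating load on the distal articular surface.

    Distributes -(sum of all applied muscle and wrap loads) equally over
    ``n_counterforce_points`` nodes of the counterforce set, so the free
    body is in translational equilibrium before solving.  Using a single
    application point is allowed but warned against (localized stress
    peaks at the force-application artifact).
    """
    k = case.n_counterforce_points
    if k < 2:
        warnings.warn(
            "fewer than 2 counterforce application points create artificially "
            "high, localized stress peaks on the articular surface",
            stacklevel=2,
        )
        k = max(k, 1)
    total = -sum((np.asarray(v) for _, v in applied), start=np.zeros(3))
    if extra_sum is not None:
        total = total - np.asarray(extra_sum, dtype=float)
    nodes = mesh.node_sets[case.counterforce_set]
    if len(nodes) == 0:
        raise ValueError(f"empty counterforce set {case.counterforce_set!r}")
    # spread the application points evenly over the set (deterministic)
    sel = nodes[np.unique(np.linspace(0, len(nodes) - 1, min(k, len(nodes))).astype(int))]
    share = total / len(sel)
    return [(int(n), share.copy()) for n in sel]


def build_case_loads(mesh: TetMesh, case: LoadCase, forces: dict | None = None):
    """Assemble the full nodal load set for a load case.

    ``forces`` optionally overrides each muscle's stored force by name.
    Two-joint muscles act on the bone only through the counterforce: their
    pull on the distal limb is added to the sum the counterforce
    equilibrates instead of being applied at their attachments.

    Returns (loads (N,3) array, report dict with the residual moment about
    the joint and per-muscle force sums).
    """
    loads = np.zeros((mesh.n_nodes, 3))
    applied = []
    two_joint_sum = np.zeros(3)
    per_muscle = {}
    for m in case.muscles:
        f = m.force if forces is None else float(forces.get(m.name, m.force))
        m_eff = MusclePath(
            name=m.name,
            roles=m.roles,
            origin=m.origin,
            insertion_set=m.insertion_set,
            via_points=m.via_points,
            subsections=m.subsections,
            force=f,
            two_joint=m.two_joint,
            rotation_sense=m.rotation_sense,
        )
        per_muscle[m.name] = f
        if m.two_joint:
            _, dirs, _ = line_of_action(m_eff, mesh, case.pose)
            two_joint_sum += f * dirs[-1]
            continue
        items = distribute_attachment_load(m_eff, mesh, case.pose)
        items += wrapping_loads(m_eff, mesh, case.pose)
        applied.extend(items)
    cf = counterforce(case, applied, mesh, extra_sum=two_joint_sum)
    for n, v in applied + cf:
        loads[n] += v
    moment = np.cross(mesh.nodes, loads).sum(axis=0)
    report = {
        "residual_moment_nmm": moment,
        "forces": per_muscle,
        "counterforce_total_n": -np.array([v for _, v in applied]).sum(axis=0) - two_joint_sum
        if applied
        else -two_joint_sum,
    }
    return loads, report


# ---------------------------------------------------------------------- #
# muscle table I/O (CSV)

_CSV_FIELDS = [
    "name",
    "roles",
    "origin_x",
    "origin_y",
    "origin_z",
    "via_points",
    "insertion_set",
    "force_n",
    "two_joint",
    "rotation_sense",
]


def write_muscle_csv(muscles: list, path) -> None:
    """Muscle table as CSV: roles ;-separated, via-points 'x y z|x y z'."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for m in muscles:
            w.writerow(
                {
                    "name": m.name,
                    "roles": ";".join(sorted(m.roles)),
                    "origin_x": repr(float(m.origin[0])),
                    "origin_y": repr(float(m.origin[1])),
                    "origin_z": repr(float(m.origin[2])),
                    "via_points": "|".join(
                        " ".join(repr(float(x)) for x in v) for v in m.via_points
                    ),
                    "insertion_set": m.insertion_set,
                    "force_n": repr(float(m.force)),
                    "two_joint": int(m.two_joint),
                    "rotation_sense": m.rotation_sense or "",
                }
            )


def read_muscle_csv(path) -> list:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            vias = [
                np.array([float(x) for x in v.split()])
                for v in row["via_points"].split("|")
                if v.strip()
            ]
            out.append(
                MusclePath(
                    name=row["name"],
                    roles=frozenset(r for r in row["roles"].split(";") if r),
                    origin=np.array(
                        [float(row["origin_x"]), float(row["origin_y"]), float(row["origin_z"])]
                    ),
                    via_points=vias,
                    insertion_set=row["insertion_set"],
                    force=float(row["force_n"]),
                    two_joint=bool(int(row["two_joint"])),
                    rotation_sense=row["rotation_sense"] or None,
                )
            )
    return out
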