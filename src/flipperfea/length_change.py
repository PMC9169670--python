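"""Muscle length changes over the flipper beat, analog-model style.

A muscle's cord length is measured (or computed from a polyline line of
action) in three flipper poses: maximum ventral excursion (~-50 deg),
neutral (0 deg), and maximum dorsal excursion (~+50 deg).  With the
neutral length set to 100%, the pose-wise percentage changes combine into

    stretching  = 100 + (largest positive change, %)
    contraction = 100 - (magnitude of the most negative change, %)
    total       = stretching - contraction

Total length change screens reconstructed muscle attachments: striated
muscle operates at roughly +/-25% around resting length, and a total
change beyond ~40% is outside the physiological envelope — an attachment
site producing, say, 70% can be rejected outright.

Percentages are rounded to two decimals *before* combination, matching
the printed arithmetic of the measurement tables this module mirrors;
cord-length changes smaller than the measurement resolution (the 1.7 cm
terminal-strip width of the analog model) are recorded as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loads import FlipperPose, MusclePath, line_of_action, pose_rotation
from .mesh import TetMesh

__all__ = [
    "CordMeasurement",
    "LengthChangeRecord",
    "PhysiologyThresholds",
    "JointPoseModel",
    "pose_lengths",
    "length_change_record",
    "classify_physiological",
    "audit_table",
    "records_frame",
]

MEASUREMENT_RESOLUTION_CM = 1.7  # width of the analog model's terminal strips


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (printed-table arithmetic)."""
    return math.floor(abs(x) * 100.0 + 0.5) / 100.0 * (1 if x >= 0 else -1)


@dataclass
class CordMeasurement:
    """Cord lengths (cm) of one muscle at the three poses."""

    muscle: str
    length_ventral: float
    length_neutral: float
    length_dorsal: float
    resolution: float = MEASUREMENT_RESOLUTION_CM

    def __post_init__(self) -> None:
        if min(self.length_ventral, self.length_neutral, self.length_dorsal) <= 0:
            raise ValueError(f"{self.muscle}: cord lengths must be positive")
        if self.resolution <= 0:
            raise ValueError("measurement resolution must be positive")


@dataclass
class LengthChangeRecord:
    """Derived percentage columns for one muscle."""

    muscle: str
    delta_ventral_cm: float
    delta_dorsal_cm: float
    delta_ventral_pct: float
    delta_dorsal_pct: float
    stretching_pct: float
    contraction_pct: float
    total_pct: float


@dataclass
class PhysiologyThresholds:
    """Screening limits: total-change flag limit and the informational
    per-direction sarcomere working range."""

    total_limit_pct: float = 40.0
    sarcomere_guide_pct: float = 25.0

    def __post_init__(self) -> None:
        if self.total_limit_pct <= 0 or self.sarcomere_guide_pct <= 0:
            raise ValueError("physiology limits must be positive")


@dataclass
class JointPoseModel:
    """Joint frame for geometric cord-length computation: elevation
    rotates the limb about the anteroposterior axis through the joint
    center; axial twist rotates about the limb long axis."""

    joint_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    long_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    elevation_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.joint_center = np.asarray(self.joint_center, dtype=float)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.elevation_axis = np.asarray(self.elevation_axis, dtype=float)
        n1, n2 = np.linalg.norm(self.long_axis), np.linalg.norm(self.elevation_axis)
        if n1 < 1e-12 or n2 < 1e-12:
            raise ValueError("degenerate joint axes")
        self.long_axis = self.long_axis / n1
        self.elevation_axis = self.elevation_axis / n2
        if abs(float(self.long_axis @ self.elevation_axis)) > 1e-9:
            raise ValueError("joint axes must be orthogonal")


def pose_lengths(
    muscle: MusclePath,
    poses,
    joint: JointPoseModel,
    mesh: TetMesh | None = None,
    insertion_point: np.ndarray | None = None,
    resolution: float = MEASUREMENT_RESOLUTION_CM,
) -> CordMeasurement:
    """Cord lengths of a muscle at (ventral, neutral, dorsal) poses, cm.

    The distal attachment (and any via-points) ride with the rotating
    limb frame; the origin stays fixed to the girdle frame.  The
    insertion is resolved from the mesh's attachment set, or given
    directly as ``insertion_point`` (mm) for mesh-free geometry.  Lengths
    are computed in mm on the polyline and reported in cm; a pose length
    within ``resolution`` of the neutral length is snapped to neutral
    (changes below the measurement resolution are recorded as zero).
    """
    down, neutral, up = poses
    if mesh is not None:
        pts, _, _ = line_of_action(muscle, mesh)
        chain = [np.asarray(p, dtype=float) for p in pts[:-1]]  # insertion + vias
    elif insertion_point is not None:
        chain = [np.asarray(insertion_point, dtype=float)] + [
            np.asarray(v, dtype=float) for v in muscle.via_points[::-1]
        ]
    else:
        raise ValueError("pose_lengths needs a mesh or an explicit insertion point")
    origin = np.asarray(muscle.origin, dtype=float)
    out = []
    for pose in (down, neutral, up):
        rot = pose_rotation(pose, joint.long_axis, joint.elevation_axis)
        posed = [rot.apply(p - joint.joint_center) + joint.joint_center for p in chain]
        length_mm = 0.0
        prev = None
        for p in posed + [origin]:
            if prev is not None:
                length_mm += float(np.linalg.norm(p - prev))
            prev = p
        out.append(length_mm / 10.0)  # mm -> cm
    l_v, l_n, l_d = out
    if abs(l_v - l_n) < resolution:
        l_v = l_n
    if abs(l_d - l_n) < resolution:
        l_d = l_n
    return CordMeasurement(muscle.name, l_v, l_n, l_d, resolution)


def length_change_record(m: CordMeasurement) -> LengthChangeRecord:
    """Derived columns from the three cord lengths.

    Percentage changes are computed against the neutral length and
    rounded to two decimals before stretching/contraction/total are
    formed, so the outputs reproduce the printed-table arithmetic.
    """
    dv_cm = m.length_ventral - m.length_neutral
    dd_cm = m.length_dorsal - m.length_neutral
    dv = _round2(100.0 * dv_cm / m.length_neutral)
    dd = _round2(100.0 * dd_cm / m.length_neutral)
    positive = max(dv, dd, 0.0)
    negative = min(dv, dd, 0.0)
    stretching = _round2(100.0 + positive)
    contraction = _round2(100.0 + negative)
    total = _round2(stretching - contraction)
    return LengthChangeRecord(
        muscle=m.muscle,
        delta_ventral_cm=dv_cm,
        delta_dorsal_cm=dd_cm,
        delta_ventral_pct=dv,
        delta_dorsal_pct=dd,
        stretching_pct=stretching,
        contraction_pct=contraction,
        total_pct=total,
    )


def classify_physiological(
    record: LengthChangeRecord, thresholds: PhysiologyThresholds | None = None
) -> tuple[bool, str]:
    """Flag a record against the physiological total-length-change limit.

    Returns (is_physiological, note).  A total exactly at the limit is
    physiological (boundary inclusive); per-direction changes beyond the
    sarcomere working range are noted but do not flip the flag.
    """
    t = thresholds or PhysiologyThresholds()
    ok = record.total_pct <= t.total_limit_pct
    notes = []
    if not ok:
        notes.append(
            f"total length change {record.total_pct:.2f}% exceeds the "
            f"~{t.total_limit_pct:.0f}% physiological limit"
        )
    for name, val in (("ventral", record.delta_ventral_pct), ("dorsal", record.delta_dorsal_pct)):
        if abs(val) > t.sarcomere_guide_pct:
            notes.append(
                f"{name} change {val:.2f}% outside the +/-{t.sarcomere_guide_pct:.0f}% "
                "sarcomere working range"
            )
    return ok, "; ".join(notes) if notes else "within physiological limits"


_FRAME_COLUMNS = [
    "muscle", "ventral_cm", "neutral_cm", "dorsal_cm",
    "delta_ventral_pct", "delta_dorsal_pct",
    "stretching_pct", "contraction_pct", "total_pct",
    "physiological", "note",
]


def records_frame(measurements) -> pd.DataFrame:
    """Derived table for a list of CordMeasurement."""
    rows = []
    for m in measurements:
        r = length_change_record(m)
        ok, note = classify_physiological(r)
        rows.append(
            {
                "muscle": r.muscle,
                "ventral_cm": m.length_ventral,
                "neutral_cm": m.length_neutral,
                "dorsal_cm": m.length_dorsal,
                "delta_ventral_pct": r.delta_ventral_pct,
                "delta_dorsal_pct": r.delta_dorsal_pct,
                "stretching_pct": r.stretching_pct,
                "contraction_pct": r.contraction_pct,
                "total_pct": r.total_pct,
                "physiological": ok,
                "note": note,
            }
        )
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def audit_table(fixture: pd.DataFrame, tolerance: float = 0.02) -> pd.DataFrame:
    """Recompute every derived column of a printed measurement table from
    its cord lengths and report rows whose printed values disagree.

    The comparison covers the cm deltas, the percentage deltas, and the
    stretching/contraction/total columns at ``tolerance``.  Inconsistent
    rows are listed with the offending columns — never corrected.
    """
    reports = []
    for _, row in fixture.iterrows():
        m = CordMeasurement(
            row["muscle"], row["ventral_cm"], row["neutral_cm"], row["dorsal_cm"]
        )
        r = length_change_record(m)
        recomputed = {
            "delta_ventral_cm": _round2(r.delta_ventral_cm),
            "delta_dorsal_cm": _round2(r.delta_dorsal_cm),
            "delta_ventral_pct": r.delta_ventral_pct,
            "delta_dorsal_pct": r.delta_dorsal_pct,
            "stretching_pct": r.stretching_pct,
            "contraction_pct": r.contraction_pct,
            "total_pct": r.total_pct,
        }
        bad = {}
        for col, val in recomputed.items():
            printed = float(row[col])
            if abs(printed - val) > tolerance:
                bad[col] = (printed, val)
        reports.append(
            {
                "flipper": row.get("flipper", ""),
                "muscle": row["muscle"],
                "consistent": not bad,
                "discrepancies": "; ".join(
                    f"{c}: printed {p:g} vs recomputed {v:g}" for c, (p, v) in bad.items()
                ),
            }
        )
    return pd.DataFrame(reports)
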