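"""Lines of action, attachment load distribution, wrapping, counterforce."""

import numpy as np
import pytest

from flipperfea.loads import (
    FlipperPose,
    LoadCase,
    MusclePath,
    build_case_loads,
    counterforce,
    distribute_attachment_load,
    line_of_action,
    pose_rotation,
    read_muscle_csv,
    wrapping_loads,
    write_muscle_csv,
)
from flipperfea.synthetic import generate_case, structured_box

from conftest import make_bar


def single_node_mesh(point=(0.0, 0.0, 0.0)):
    """Bar mesh with a one-node attachment set at the node nearest ``point``."""
    mesh = make_bar(nx=4)
    idx = int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(point), axis=1)))
    mesh.node_sets["ins"] = np.array([idx])
    return mesh, idx


class TestLineOfAction:
    def test_straight_muscle_single_segment(self):
        mesh, idx = single_node_mesh()
        m = MusclePath("m", frozenset({"depressor"}), np.array([-100.0, 0, 0]), "ins")
        pts, dirs, length = line_of_action(m, mesh)
        assert len(pts) == 2
        expected = (m.origin - mesh.nodes[idx]) / np.linalg.norm(m.origin - mesh.nodes[idx])
        np.testing.assert_allclose(dirs[0], expected)

    def test_collinear_via_same_length(self):
        mesh, idx = single_node_mesh()
        start = mesh.nodes[idx]
        origin = start + np.array([-90.0, 0, 0])
        via = start + np.array([-30.0, 0, 0])
        straight = MusclePath("a", frozenset({"depressor"}), origin, "ins")
        kinked = MusclePath("b", frozenset({"depressor"}), origin, "ins", via_points=[via])
        _, _, l1 = line_of_action(straight, mesh)
        _, _, l2 = line_of_action(kinked, mesh)
        assert l2 == pytest.approx(l1)

    def test_right_angle_polyline_pythagoras(self):
        """3-4-5 triangle: polyline through the corner measures 7, the
        straight chord 5."""
        mesh, idx = single_node_mesh()
        start = mesh.nodes[idx]
        via = start + np.array([0.0, 0.0, 3.0])
        origin = via + np.array([0.0, 4.0, 0.0])
        m = MusclePath("m", frozenset({"flexor"}), origin, "ins", via_points=[via])
        _, _, length = line_of_action(m, mesh)
        assert length == pytest.approx(7.0)
        chord = np.linalg.norm(origin - start)
        assert chord == pytest.approx(5.0)

    def test_zero_length_segment_names_muscle(self):
        mesh, idx = single_node_mesh()
        m = MusclePath("bad_muscle", frozenset({"flexor"}), mesh.nodes[idx].copy(), "ins")
        with pytest.raises(ValueError, match="bad_muscle"):
            line_of_action(m, mesh)


class TestAttachmentLoads:
    def test_force_conserved_over_four_nodes(self):
        mesh = make_bar(nx=4)
        face = mesh.node_sets["x0_face"][:4]
        mesh.node_sets["ins"] = face
        m = MusclePath(
            "m", frozenset({"depressor"}), np.array([-1000.0, 5.0, 5.0]), "ins", force=9600.0
        )
        loads = distribute_attachment_load(m, mesh)
        assert len(loads) == 4
        magnitudes = [np.linalg.norm(v) for _, v in loads]
        np.testing.assert_allclose(magnitudes, 2400.0, rtol=1e-6)
        total = np.sum([v for _, v in loads], axis=0)
        assert np.linalg.norm(total) == pytest.approx(9600.0, rel=1e-9)

    def test_single_node_full_force(self):
        mesh, _ = single_node_mesh()
        m = MusclePath("m", frozenset({"flexor"}), np.array([-100.0, 5, 5]), "ins", force=123.0)
        loads = distribute_attachment_load(m, mesh)
        assert len(loads) == 1
        assert np.linalg.norm(loads[0][1]) == pytest.approx(123.0)

    def test_perpendicular_subsections_resultant(self):
        """Two equal-weight subsections at right angles: |resultant| of a
        100 N muscle is 100/sqrt(2) = 70.71 N."""
        mesh, _ = single_node_mesh()
        m = MusclePath(
            "m",
            frozenset({"flexor"}),
            np.array([-100.0, 5, 5]),
            "ins",
            subsections=[(0.5, np.array([1.0, 0, 0])), (0.5, np.array([0.0, 1, 0]))],
            force=100.0,
        )
        loads = distribute_attachment_load(m, mesh)
        total = np.sum([v for _, v in loads], axis=0)
        assert np.linalg.norm(total) == pytest.approx(100.0 / np.sqrt(2), rel=1e-9)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MusclePath(
                "m", frozenset({"flexor"}), np.zeros(3), "ins",
                subsections=[(0.5, None), (0.3, None)],
            )


class TestWrappingLoads:
    def contact_sum(self, via_offset, origin_offset, force=100.0):
        """Net via contact for insertion -> via -> origin geometry placed
        just outside the bar's top surface."""
        mesh, idx = single_node_mesh(point=(50.0, 5.0, 10.0))
        start = mesh.nodes[idx]
        via = start + np.asarray(via_offset, dtype=float)
        origin = via + np.asarray(origin_offset, dtype=float)
        m = MusclePath(
            "m", frozenset({"elevator"}), origin, "ins", via_points=[via], force=force
        )
        loads = wrapping_loads(m, mesh, drop_liftoff=False)
        return np.sum([v for _, v in loads], axis=0)

    def test_right_angle_bend(self):
        """90 degree bend: contact magnitude sqrt(2) * F along the bisector."""
        total = self.contact_sum(via_offset=(-30.0, 0, 0), origin_offset=(0, 0, -40.0))
        assert np.linalg.norm(total) == pytest.approx(np.sqrt(2) * 100.0, rel=1e-9)
        np.testing.assert_allclose(
            total / np.linalg.norm(total), np.array([1, 0, -1]) / np.sqrt(2), atol=1e-9
        )

    def test_straight_path_no_contact(self):
        total = self.contact_sum(via_offset=(-30.0, 0, 0), origin_offset=(-40.0, 0, 0))
        assert np.linalg.norm(total) < 1e-9

    def test_full_wrap_doubles_force(self):
        total = self.contact_sum(via_offset=(-30.0, 0, 0), origin_offset=(40.0, 0, 0))
        assert np.linalg.norm(total) == pytest.approx(200.0, rel=1e-9)

    def test_liftoff_dropped_with_warning(self):
        """A via contact pointing out of the surface is dropped: the cord
        runs level along the top face and then climbs steeply away, so
        the bend pushes upward (outward) at the via."""
        mesh, idx = single_node_mesh(point=(50.0, 5.0, 10.0))
        start = mesh.nodes[idx]
        via = start + np.array([-30.0, 0.0, 0.0])  # on the top surface
        origin = via + np.array([-10.0, 0.0, 60.0])  # cord climbs away
        m = MusclePath("m", frozenset({"elevator"}), origin, "ins", via_points=[via], force=10.0)
        with pytest.warns(UserWarning, match="lifts off"):
            loads = wrapping_loads(m, mesh)
        assert loads == []


class TestCounterforce:
    @pytest.fixture()
    def bar_case(self):
        mesh = make_bar(nx=4, ny=3, nz=3)  # 16 nodes on each end face
        mesh.node_sets["distal_articular"] = mesh.node_sets["x1_face"]
        return mesh

    def test_equilibrates_single_muscle(self, bar_case):
        applied = [(0, np.array([-1000.0, 0.0, 0.0]))]
        case = LoadCase(
            pose=FlipperPose(0, 0, "neutral"),
            muscles=_dummy_pair(),
            n_counterforce_points=6,
        )
        loads = counterforce(case, applied, bar_case)
        total = np.sum([v for _, v in loads], axis=0)
        np.testing.assert_allclose(total, [1000.0, 0.0, 0.0], atol=1e-9)

    def test_equal_split_over_points(self, bar_case):
        applied = [(0, np.array([-500.0, 0.0, 0.0]))]
        case = LoadCase(
            pose=FlipperPose(0, 0, "neutral"),
            muscles=_dummy_pair(),
            n_counterforce_points=10,
        )
        loads = counterforce(case, applied, bar_case)
        assert len(loads) == 10
        for _, v in loads:
            np.testing.assert_allclose(v, [50.0, 0.0, 0.0], atol=1e-12)

    def test_single_point_warns(self, bar_case):
        applied = [(0, np.array([-1.0, 0.0, 0.0]))]
        case = LoadCase(
            pose=FlipperPose(0, 0, "neutral"),
            muscles=_dummy_pair(),
            n_counterforce_points=1,
        )
        with pytest.warns(UserWarning, match="stress peaks"):
            counterforce(case, applied, bar_case)

    def test_mirrored_pair_cancels_dorsoventral(self, bar_case):
        applied = [
            (0, np.array([-100.0, 0.0, 250.0])),
            (1, np.array([-100.0, 0.0, -250.0])),
        ]
        case = LoadCase(pose=FlipperPose(0, 0, "neutral"), muscles=_dummy_pair())
        loads = counterforce(case, applied, bar_case)
        total = np.sum([v for _, v in loads], axis=0)
        assert total[2] == pytest.approx(0.0, abs=1e-12)
        assert total[0] == pytest.approx(200.0)


class TestPoses:
    def test_rotation_preserves_lengths_and_angles(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 3)) * 50.0
        rot = pose_rotation(FlipperPose(-50.0, -19.0, "downstroke"))
        posed = rot.apply(pts)
        d0 = np.linalg.norm(pts[1:] - pts[:-1], axis=1)
        d1 = np.linalg.norm(posed[1:] - posed[:-1], axis=1)
        np.testing.assert_allclose(d0, d1, rtol=1e-12)
        assert np.linalg.det(rot.as_matrix()) == pytest.approx(1.0, abs=1e-12)

    def test_pose_label_sign_conventions(self):
        with pytest.raises(ValueError, match="downstroke"):
            FlipperPose(0.0, 19.0, "downstroke")
        with pytest.raises(ValueError, match="upstroke"):
            FlipperPose(0.0, -19.0, "upstroke")
        with pytest.raises(ValueError, match="elevation"):
            FlipperPose(80.0, 0.0, "neutral")

    def test_load_case_needs_both_sides(self):
        m = MusclePath("d", frozenset({"depressor"}), np.array([-1.0, 0, 0]), "ins")
        with pytest.raises(ValueError, match="antagonist"):
            LoadCase(pose=FlipperPose(0, -19.0, "downstroke"), muscles=[m])


class TestFullLoadSet:
    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_translational_equilibrium_any_forces(self, seed):
        """The complete load set is in translational equilibrium for any
        force assignment and pose."""
        case = generate_case(seed=1, with_known_forces=False)
        rng = np.random.default_rng(seed)
        forces = {m.name: float(rng.uniform(5.0, 5000.0)) for m in case.muscles}
        for label, twist in (("downstroke", -19.0), ("upstroke", 19.0)):
            lc = LoadCase(pose=FlipperPose(0.0, twist, label), muscles=case.muscles)
            loads, _ = build_case_loads(case.mesh, lc, forces=forces)
            scale = np.abs(loads).sum()
            assert np.abs(loads.sum(axis=0)).max() < 1e-9 * scale

    def test_two_joint_muscle_contributes_via_counterforce_only(self):
        mesh = make_bar(nx=4)
        mesh.node_sets["distal_articular"] = mesh.node_sets["x1_face"]
        mesh.node_sets["proximal_cartilage_top"] = mesh.node_sets["x1_face"]
        mesh.node_sets["ins"] = mesh.node_sets["x0_face"][:2]
        two_joint = MusclePath(
            "tj", frozenset({"flexor"}), np.array([-100.0, 5, 5]), "ins",
            force=100.0, two_joint=True,
        )
        partner = MusclePath(
            "p", frozenset({"extensor"}), np.array([-100.0, 5, 5]), "ins", force=50.0
        )
        lc = LoadCase(pose=FlipperPose(0, 0, "neutral"), muscles=[two_joint, partner])
        loads, report = build_case_loads(mesh, lc)
        # the two-joint pull is transmitted through the counterforce only,
        # so the bone's net load equals minus that transmitted vector
        # (carried by the fixed boundary), not zero
        pts, dirs, _ = line_of_action(two_joint, mesh)
        transmitted = 100.0 * dirs[-1]
        np.testing.assert_allclose(loads.sum(axis=0), -transmitted, atol=1e-9)
        # and no nodal load sits on the attachment beyond the partner's 50 N
        ins_nodes = mesh.node_sets["ins"]
        assert np.linalg.norm(loads[ins_nodes].sum(axis=0)) == pytest.approx(50.0, rel=1e-9)

    def test_muscle_csv_round_trip(self, tmp_path):
        case = generate_case(seed=5, with_known_forces=False)
        path = tmp_path / "muscles.csv"
        write_muscle_csv(case.muscles, path)
        back = read_muscle_csv(path)
        assert [m.name for m in back] == [m.name for m in case.muscles]
        for a, b in zip(case.muscles, back):
            assert a.roles == b.roles
            np.testing.assert_array_equal(a.origin, b.origin)
            assert len(a.via_points) == len(b.via_points)
            assert a.two_joint == b.two_joint


def _dummy_pair():
    return [
        MusclePath("d", frozenset({"depressor"}), np.array([-1.0, 0, 0]), "ins"),
        MusclePath("e", frozenset({"elevator"}), np.array([-1.0, 0, 0]), "ins"),
    ]
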