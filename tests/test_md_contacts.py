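"""Contact detectors against constructed boundaries and a brute-force oracle."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motorforge.md_contacts import (
    ContactCriteria,
    ContactError,
    ContactPair,
    ResidueSpec,
    detect_hbond,
    detect_hydrophobic,
    detect_salt_bridge,
    occupancy,
)
from motorforge.structures import StructureFrame, Trajectory
from motorforge.synthetic_data import (
    ContactSchedule,
    SyntheticTrajectoryParams,
    simulate_mtbd_trajectory,
)


def _frame(records):
    chain, rid, rname, aname, elem, xyz = zip(*records)
    return StructureFrame(chain_id=np.array(chain), res_id=np.array(rid),
                          res_name=np.array(rname),
                          atom_name=np.array(aname),
                          element=np.array(elem), coord=np.array(xyz))


def _arg_glu_frame(min_no_distance):
    return _frame([
        ("A", 1, "ARG", "NE", "N", [0.0, 0.0, 0.0]),
        ("A", 1, "ARG", "NH1", "N", [-1.0, 1.2, 0.0]),
        ("B", 2, "GLU", "OE1", "O", [min_no_distance, 0.0, 0.0]),
        ("B", 2, "GLU", "OE2", "O", [min_no_distance + 2.0, 0.0, 0.0]),
    ])


SB_PAIR = ContactPair(kind="salt_bridge", residue_a=ResidueSpec("A", 1),
                      residue_b=ResidueSpec("B", 2))


class TestSaltBridge:
    @pytest.mark.parametrize("dist,expected", [
        (3.9, True), (4.0, True), (4.1, False)])
    def test_closed_boundary_at_4A(self, dist, expected):
        assert detect_salt_bridge(_arg_glu_frame(dist), SB_PAIR) is expected

    def test_non_basic_residue_rejected(self):
        frame = _frame([
            ("A", 1, "ALA", "CB", "C", [0.0, 0.0, 0.0]),
            ("B", 2, "GLU", "OE1", "O", [3.0, 0.0, 0.0])])
        with pytest.raises(ContactError):
            detect_salt_bridge(frame, SB_PAIR)

    def test_histidine_can_be_excluded(self):
        frame = _frame([
            ("A", 1, "HIS", "ND1", "N", [0.0, 0.0, 0.0]),
            ("B", 2, "ASP", "OD1", "O", [3.0, 0.0, 0.0])])
        assert detect_salt_bridge(frame, SB_PAIR)
        with pytest.raises(ContactError):
            detect_salt_bridge(frame, SB_PAIR,
                               ContactCriteria(include_histidine=False))


def _hbond_frame(d_da, angle_deg):
    # donor at origin; acceptor at distance d_da along x; hydrogen placed so
    # that the H-donor-acceptor angle equals angle_deg
    rad = math.radians(angle_deg)
    h = [math.cos(rad), math.sin(rad), 0.0]
    return _frame([
        ("A", 1, "SER", "OG", "O", [0.0, 0.0, 0.0]),
        ("A", 1, "SER", "HG1", "H", h),
        ("B", 2, "VAL", "O", "O", [d_da, 0.0, 0.0])])


HB_PAIR = ContactPair(kind="hbond", residue_a=ResidueSpec("A", 1),
                      residue_b=ResidueSpec("B", 2), donor_atom="OG",
                      hydrogen_atom="HG1", acceptor_atom="O")


class TestHbond:
    @pytest.mark.parametrize("d,ang,expected", [
        (3.4, 25.0, True), (3.4, 35.0, False), (3.6, 10.0, False),
        (3.5, 30.0, True)])
    def test_distance_and_angle_criteria(self, d, ang, expected):
        assert detect_hbond(_hbond_frame(d, ang), HB_PAIR) is expected

    def test_missing_hydrogen_reported(self):
        frame = _frame([
            ("A", 1, "SER", "OG", "O", [0.0, 0.0, 0.0]),
            ("B", 2, "VAL", "O", "O", [3.0, 0.0, 0.0])])
        with pytest.raises(ContactError, match="hydrogen"):
            detect_hbond(frame, HB_PAIR)


def _pair_frame_hydrophobic(cb_cb, backbone_dist=None):
    records = [
        ("A", 1, "LEU", "CB", "C", [0.0, 0.0, 0.0]),
        ("A", 1, "LEU", "CA", "C", [-1.5, 0.0, 0.0]),
        ("B", 2, "VAL", "CB", "C", [cb_cb, 0.0, 0.0]),
        ("B", 2, "VAL", "CA", "C", [cb_cb + 1.5, 0.0, 0.0]),
    ]
    if backbone_dist is not None:
        records.append(("A", 1, "LEU", "C", "C", [0.0, 2.0, 0.0]))
        records.append(("B", 2, "VAL", "C", "C",
                        [backbone_dist, 2.0, 0.0]))
    return _frame(records)


HP_PAIR = ContactPair(kind="hydrophobic", residue_a=ResidueSpec("A", 1),
                      residue_b=ResidueSpec("B", 2))


class TestHydrophobic:
    def test_side_chain_contact_at_7p5(self):
        assert detect_hydrophobic(_pair_frame_hydrophobic(7.5), HP_PAIR)

    def test_exact_8A_counts(self):
        assert detect_hydrophobic(_pair_frame_hydrophobic(8.0), HP_PAIR)

    def test_backbone_carbons_do_not_count(self):
        # side chains far apart but backbone C atoms at 6 A
        frame = _pair_frame_hydrophobic(12.0, backbone_dist=6.0)
        assert not detect_hydrophobic(frame, HP_PAIR)

    def test_glycine_partner_reported(self):
        frame = _frame([
            ("A", 1, "GLY", "CA", "C", [0.0, 0.0, 0.0]),
            ("B", 2, "VAL", "CB", "C", [3.0, 0.0, 0.0])])
        with pytest.raises(ContactError):
            detect_hydrophobic(frame, HP_PAIR)


# ---------------------------------------------------------------------------
# brute-force oracle (independent, loop-based re-implementation)
# ---------------------------------------------------------------------------

def _oracle_salt_bridge(frame, cutoff=4.0):
    basic = {"LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"],
             "HIS": ["ND1", "NE2"]}
    acidic = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
    ns, os_ = [], []
    for i in range(len(frame)):
        rn, an = frame.res_name[i], frame.atom_name[i]
        if frame.res_id[i] == 1 and an in basic.get(rn, []):
            ns.append(frame.coord[i])
        if frame.res_id[i] == 2 and (an in acidic.get(rn, [])
                                     or an == "OXT"):
            os_.append(frame.coord[i])
    best = min(math.dist(n, o) for n in ns for o in os_)
    return best <= cutoff


def _oracle_hydrophobic(frame, cutoff=8.0):
    backbone = {"N", "CA", "C", "O", "OXT"}
    a, b = [], []
    for i in range(len(frame)):
        if frame.element[i] != "C" or frame.atom_name[i] in backbone:
            continue
        (a if frame.res_id[i] == 1 else b).append(frame.coord[i])
    return min(math.dist(x, y) for x in a for y in b) <= cutoff


def _oracle_hbond(frame, d_cut=3.5, ang_cut=30.0):
    idx = {frame.atom_name[i]: frame.coord[i] for i in range(len(frame))}
    d, h, a = idx["OG"], idx["HG1"], idx["O"]
    if math.dist(d, a) > d_cut:
        return False
    v1 = [h[k] - d[k] for k in range(3)]
    v2 = [a[k] - d[k] for k in range(3)]
    dot = sum(x * y for x, y in zip(v1, v2))
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))
    return ang <= ang_cut


class TestBruteForceOracle:
    def test_salt_bridge_matches_oracle_on_random_frames(self):
        rng = np.random.default_rng(20)
        for _ in range(400):
            frame = _frame([
                ("A", 1, "ARG", "NE", "N", rng.uniform(-3, 3, 3)),
                ("A", 1, "ARG", "NH1", "N", rng.uniform(-3, 3, 3)),
                ("A", 1, "ARG", "NH2", "N", rng.uniform(-3, 3, 3)),
                ("B", 2, "GLU", "OE1", "O", rng.uniform(-3, 3, 3)),
                ("B", 2, "GLU", "OE2", "O", rng.uniform(-3, 3, 3))])
            assert detect_salt_bridge(frame, SB_PAIR) == \
                _oracle_salt_bridge(frame)

    def test_hydrophobic_matches_oracle_on_random_frames(self):
        rng = np.random.default_rng(21)
        for _ in range(400):
            frame = _frame([
                ("A", 1, "LEU", "CB", "C", rng.uniform(-6, 6, 3)),
                ("A", 1, "LEU", "CD1", "C", rng.uniform(-6, 6, 3)),
                ("A", 1, "LEU", "CA", "C", rng.uniform(-6, 6, 3)),
                ("B", 2, "VAL", "CB", "C", rng.uniform(-6, 6, 3)),
                ("B", 2, "VAL", "CG1", "C", rng.uniform(-6, 6, 3)),
                ("B", 2, "VAL", "C", "C", rng.uniform(-6, 6, 3))])
            assert detect_hydrophobic(frame, HP_PAIR) == \
                _oracle_hydrophobic(frame)

    def test_hbond_matches_oracle_on_random_frames(self):
        rng = np.random.default_rng(22)
        for _ in range(400):
            frame = _frame([
                ("A", 1, "SER", "OG", "O", rng.uniform(-2, 2, 3)),
                ("A", 1, "SER", "HG1", "H", rng.uniform(-2, 2, 3)),
                ("B", 2, "VAL", "O", "O", rng.uniform(-2, 2, 3))])
            assert detect_hbond(frame, HB_PAIR) == _oracle_hbond(frame)

    def test_detection_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(23)
        for seed in range(50):
            frame = _arg_glu_frame(3.5 + rng.uniform(0, 1))
            rot = Rotation.random(random_state=seed)
            moved = frame.with_coord(rot.apply(frame.coord)
                                     + rng.uniform(-50, 50, 3))
            assert detect_salt_bridge(frame, SB_PAIR) == \
                detect_salt_bridge(moved, SB_PAIR)


class TestOccupancy:
    def _traj(self, pattern, n_frames):
        sched = ContactSchedule(pattern=pattern)
        return simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            n_frames=n_frames, contact_schedule=sched, seed=30)).frames

    PAIR = ContactPair(kind="salt_bridge", residue_a=ResidueSpec("A", 402),
                       residue_b=ResidueSpec("D", 3306))

    def test_always_on_gives_unit_occupancy(self):
        res = occupancy(self._traj([True], 50), self.PAIR)
        assert res.pooled == 1.0

    def test_alternating_schedule_is_exactly_half(self):
        res = occupancy(self._traj([True, False], 1000), self.PAIR)
        assert res.pooled == 0.5

    def test_pooling_over_trajectories(self):
        t1 = self._traj([True] * 2 + [False] * 8, 100)    # 0.2
        t2 = self._traj([True] * 8 + [False] * 2, 100)    # 0.8
        res = occupancy([t1, t2], self.PAIR)
        assert res.per_trajectory == pytest.approx([0.2, 0.8])
        assert res.pooled == pytest.approx(0.5)
        assert res.n_trajectories == 2

    def test_programmed_occupancy_exact(self):
        pattern = [True] * 624 + [False] * 376
        res = occupancy(self._traj(pattern, 1000), self.PAIR)
        assert res.pooled == 0.624
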