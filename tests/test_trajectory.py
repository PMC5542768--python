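"""Distance series, minimum-distance traces and displacement summaries."""

import numpy as np
import pytest

from conftest import random_rigid
from xldock.restraints import DistanceRestraint, RestraintSet, build_restraints
from xldock.structures import Structure, Trajectory, get_anchor_atom
from xldock.synthetic import perturb_trajectory, simulate_pairwise
from xldock.trajectory import (
    RunProtocol,
    displacement_summary,
    min_distance_series,
    restraint_series,
)


@pytest.fixture(scope="module")
def swayed(planted):
    cx, truth = planted
    traj, motion = perturb_trajectory(cx, n_frames=12, amplitude=6.0, mode="global_sway")
    return cx, truth, traj, motion


class TestRestraintSeries:
    def test_static_trajectory_constant_series(self, planted):
        cx, truth = planted
        rs = build_restraints(simulate_pairwise(cx, truth))
        traj = Trajectory([cx.copy() for _ in range(10)])
        series = restraint_series(traj, rs)
        assert len(series) == len(rs)
        for s in series:
            assert np.ptp(s.distances) == 0.0
            assert s.fraction_within in (0.0, 1.0)

    def test_linear_motion_matches_closed_form(self, swayed):
        cx, truth, traj, motion = swayed
        rs = build_restraints(simulate_pairwise(cx, truth))
        series = restraint_series(traj, rs)
        for r, s in zip(rs, series):
            a = get_anchor_atom(cx, ("L", r.seq_a), r.anchor_a).xyz
            b = get_anchor_atom(cx, ("R", r.seq_b), r.anchor_b).xyz
            expected = motion.expected_distance(a, b)
            np.testing.assert_allclose(s.distances, expected, atol=1e-6)

    def test_fraction_within_counts_crossing_frames(self, swayed):
        cx, truth, traj, motion = swayed
        rs = build_restraints(simulate_pairwise(cx, truth))
        series = restraint_series(traj, rs)
        for r, s in zip(rs, series):
            a = get_anchor_atom(cx, ("L", r.seq_a), r.anchor_a).xyz
            b = get_anchor_atom(cx, ("R", r.seq_b), r.anchor_b).xyz
            expected = motion.expected_distance(a, b)
            assert s.fraction_within == pytest.approx(np.mean(expected <= r.d0))

    def test_fraction_within_monotone_in_d0(self, swayed):
        cx, truth, traj, _ = swayed
        rs = build_restraints(simulate_pairwise(cx, truth))
        base = restraint_series(traj, rs)[0]
        fracs = []
        for d0 in (2.0, 6.0, 10.0, 14.0, 30.0):
            s = base.__class__(base.series_id, base.distances, base.frame_labels, d0=d0)
            fracs.append(s.fraction_within)
        assert fracs == sorted(fracs)


class TestMinDistanceSeries:
    def test_single_target_atom_equals_pair_series(self, planted):
        cx, truth = planted
        traj = Trajectory([cx.copy() for _ in range(3)])
        # reduce ligand chain to one atom so min == plain pair distance
        frames = []
        for frame in traj.frames:
            residues = [r for r in frame if r.ref.chain == "R"]
            lig = [r for r in frame if r.ref.chain == "L"][0]
            lig.atoms = [lig.atoms[0]]
            residues.append(lig)
            frames.append(Structure(residues))
        small = Trajectory(frames)
        probe = ("R", 1)
        s = min_distance_series(small, probe, "L")
        cb = get_anchor_atom(frames[0], probe, "CB").xyz
        expected = float(np.linalg.norm(frames[0].coords(chain="L")[0] - cb))
        np.testing.assert_allclose(s.distances, expected, atol=1e-9)

    def test_matches_brute_force_over_target_atoms(self, swayed):
        cx, truth, traj, _ = swayed
        probe = ("R", 5)
        s = min_distance_series(traj, probe, "L")
        for k, frame in enumerate(traj.frames):
            cb = get_anchor_atom(frame, probe, "CB").xyz
            target = frame.coords(chain="L", heavy_only=True)
            oracle = float(np.min(np.linalg.norm(target - cb, axis=1)))
            assert s.distances[k] == pytest.approx(oracle, abs=1e-9)

    def test_crossing_constructed_at_known_frame(self, planted):
        cx, truth = planted
        # move one receptor loop residue straight toward the ligand
        probe = ("R", 1)
        traj, _ = perturb_trajectory(
            cx, n_frames=10, amplitude=8.0, mode="local_loop", loop_residue=probe,
            axis=tuple(
                (cx.coords(chain="L").mean(axis=0)
                 - get_anchor_atom(cx, probe, "CB").xyz)
            ),
        )
        s = min_distance_series(traj, probe, "L", threshold=9.0)
        # distances shrink monotonically toward the ligand
        assert s.distances[-1] < s.distances[0]
        assert np.all(np.diff(s.distances) <= 1e-9)

    def test_series_minimum_recovered(self, planted):
        cx, _ = planted
        probe = ("R", 1)
        target = cx.coords(chain="L").mean(axis=0)
        start = get_anchor_atom(cx, probe, "CB").xyz
        gap = float(np.linalg.norm(target - start))
        traj, motion = perturb_trajectory(
            cx, n_frames=5, amplitude=2.0, mode="local_loop", loop_residue=probe,
            axis=tuple(target - start),
        )
        s = min_distance_series(traj, probe, "L")
        assert s.distances.min() == pytest.approx(s.distances[-1])


class TestDisplacementSummary:
    def test_identical_frames_are_all_zero(self, planted):
        cx, _ = planted
        traj = Trajectory([cx.copy() for _ in range(4)])
        region = {("L", r.ref.seq) for r in cx if r.ref.chain == "L"}
        anchor = {("R", r.ref.seq) for r in cx if r.ref.chain == "R"}
        summary = displacement_summary(traj, region, anchor_region=anchor)
        np.testing.assert_allclose(summary.centroid_displacement, 0.0, atol=1e-9)
        np.testing.assert_allclose(summary.rmsd, 0.0, atol=1e-9)

    def test_rigid_translation_of_region_with_fixed_anchor(self, planted):
        cx, _ = planted
        traj, _ = perturb_trajectory(cx, n_frames=2, amplitude=5.0, mode="global_sway",
                                     axis=(0.0, 0.0, 1.0))
        region = {("L", r.ref.seq) for r in cx if r.ref.chain == "L"}
        anchor = {("R", r.ref.seq) for r in cx if r.ref.chain == "R"}
        summary = displacement_summary(traj, region, anchor_region=anchor)
        assert summary.centroid_displacement[0] == pytest.approx(0.0, abs=1e-9)
        assert summary.centroid_displacement[1] == pytest.approx(5.0, abs=1e-6)
        assert summary.max_displacement == pytest.approx(5.0, abs=1e-6)

    def test_rmsd_matches_independent_kabsch_oracle(self, planted, rng):
        cx, _ = planted
        frame2 = cx.copy()
        for res in frame2:
            for a in res.atoms:
                a.xyz = a.xyz + rng.normal(0, 0.3, 3)
        traj = Trajectory([cx.copy(), frame2])
        region = {("L", r.ref.seq) for r in cx if r.ref.chain == "L"}
        anchor = {("R", r.ref.seq) for r in cx if r.ref.chain == "R"}
        summary = displacement_summary(traj, region, anchor_region=anchor)

        def backbone(st, keys):
            pts = []
            for c, s in sorted(keys):
                res = st.get_residue(c, s)
                for name in ("N", "CA", "C"):
                    if res.has_atom(name):
                        pts.append(res.atom(name).xyz)
            return np.array(pts)

        # independent Kabsch superposition on the anchor region
        mob, ref = backbone(frame2, anchor), backbone(cx, anchor)
        mc, rc = mob.mean(0), ref.mean(0)
        H = (mob - mc).T @ (ref - rc)
        U, S, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        moved = (backbone(frame2, region) - mc) @ R.T + rc
        oracle = float(np.sqrt(np.mean(np.sum((moved - backbone(cx, region)) ** 2, axis=1))))
        assert summary.rmsd[1] == pytest.approx(oracle, abs=1e-6)

    def test_invariant_under_global_transform_of_everything(self, planted, rng):
        cx, _ = planted
        traj, _ = perturb_trajectory(cx, n_frames=3, amplitude=4.0, mode="global_sway")
        region = {("L", r.ref.seq) for r in cx if r.ref.chain == "L"}
        anchor = {("R", r.ref.seq) for r in cx if r.ref.chain == "R"}
        base = displacement_summary(traj, region, anchor_region=anchor)
        Q, t = random_rigid(rng)
        moved = Trajectory([f.transformed(Q, t) for f in traj.frames])
        other = displacement_summary(moved, region, anchor_region=anchor)
        np.testing.assert_allclose(
            other.centroid_displacement, base.centroid_displacement, atol=1e-6
        )
        np.testing.assert_allclose(other.rmsd, base.rmsd, atol=1e-6)

    def test_empty_region_is_an_error(self, planted):
        cx, _ = planted
        with pytest.raises(ValueError, match="empty"):
            displacement_summary(Trajectory([cx.copy()]), set())


class TestRunProtocol:
    def test_restrained_mask_splits_at_cutoff(self):
        proto = RunProtocol(restrained_until=20.0, weight=10.0)
        labels = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        np.testing.assert_array_equal(
            proto.restrained_mask(labels), [True, True, True, False, False]
        )
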