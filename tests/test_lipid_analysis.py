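"""Gate-plane fitting, lipid tilt, membrane insertion, and egress order."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from barrelgate.exceptions import DegenerateGeometryError
from barrelgate.lipid_analysis import (
    GatePlane,
    InsertionSeries,
    LipidDefinition,
    egress_order,
    fit_gate_plane,
    insertion_series,
    tilt_series,
)
from barrelgate.structure_io import Trajectory
from barrelgate.synthetic_data import SyntheticSpec, generate_trajectory

from conftest import ca_structure, make_structure, static_trajectory


def head_trajectory(pa, pb, n_frames=1):
    s = make_structure([
        ("PA", "LPA", 900, "L", "P", pa),
        ("PB", "LPA", 900, "L", "P", pb),
        ("C1", "LPT", 901, "L", "C", (9, 9, 9)),
    ])
    return static_trajectory(s, n_frames)


HEAD_ONLY = LipidDefinition(pa_atom=0, pb_atom=1, tails=((2,),))


class TestFitGatePlane:
    def test_axis_oriented_plane(self):
        s = ca_structure([(1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)])
        plane = fit_gate_plane(s, [1, 2, 3, 4], axis_point=(0, 0, 0.5))
        np.testing.assert_allclose(plane.normal, [1, 0, 0], atol=1e-12)
        assert plane.signed_distance(np.array([[2, 0.5, 0.5]]))[0] == pytest.approx(1.0)

    def test_collinear_flank_rejected(self):
        s = ca_structure([(1, 0, 0), (2, 0, 0), (3, 0, 0)])
        with pytest.raises(DegenerateGeometryError):
            fit_gate_plane(s, [1, 2, 3], axis_point=(0, 0, 0))

    def test_noisy_plane_recovered_vs_direct_minimization(self, rng):
        """SVD fit matches direct minimization of squared point-plane distance
        and recovers a known noisy plane's normal within 2°."""
        true_n = np.array([1.0, 2.0, -0.5])
        true_n /= np.linalg.norm(true_n)
        basis = np.linalg.svd(true_n[None])[2][1:]
        uv = rng.uniform(-5, 5, (40, 2))
        pts = uv @ basis + rng.normal(scale=0.1, size=(40, 3)) + 3.0 * true_n

        def cost(x):
            th, ph = x
            n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
            d = pts @ n
            return np.sum((d - d.mean()) ** 2)

        best = min(
            (minimize(cost, x0, method="Nelder-Mead") for x0 in
             [(0.1, 0.1), (1.0, 2.0), (2.0, -1.0), (1.5, 0.5)]),
            key=lambda r: r.fun,
        )
        th, ph = best.x
        oracle_n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

        s = ca_structure(pts)
        plane = fit_gate_plane(s, list(range(1, 41)), axis_point=(-50, -100, 25))
        for ref in (true_n, oracle_n):
            ang = np.degrees(np.arccos(abs(np.clip(plane.normal @ ref, -1, 1))))
            assert ang < 2.0

    def test_normal_must_be_unit(self):
        with pytest.raises(DegenerateGeometryError):
            GatePlane(point=(0, 0, 0), normal=(1, 1, 0))


class TestTiltSeries:
    @pytest.mark.parametrize("pb,expected", [
        ((0, 0, 1), 0.0),
        ((0, 0, -1), 180.0),
        ((1, 0, -1), 135.0),
        ((1, 0, 0), 90.0),
    ])
    def test_reference_angles(self, pb, expected):
        ts = tilt_series(head_trajectory((0, 0, 0), pb), HEAD_ONLY)
        assert ts.angles[0] == pytest.approx(expected, abs=1e-9)

    def test_coincident_heads_flagged_not_raised(self):
        ts = tilt_series(head_trajectory((0, 0, 0), (0, 0, 1e-9)), HEAD_ONLY)
        assert np.isnan(ts.angles[0])
        assert ts.counts.sum() == 0

    def test_histogram_resolves_112_5_boundary(self):
        ts = tilt_series(head_trajectory((0, 0, 0), (0, 0, 1)), HEAD_ONLY, bin_width=2.5)
        assert 112.5 in ts.bin_edges

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.tuples(*[st.floats(-5, 5) for _ in range(3)]))
    def test_pa_pb_swap_supplements_to_180(self, vec):
        v = np.asarray(vec)
        if np.linalg.norm(v) < 1e-3:
            return
        ts = tilt_series(head_trajectory((0, 0, 0), v), HEAD_ONLY)
        swapped = tilt_series(head_trajectory(v, (0, 0, 0)), HEAD_ONLY)
        assert ts.angles[0] + swapped.angles[0] == pytest.approx(180.0, abs=1e-9)

    def test_invariance_to_rotation_about_axis(self, rng):
        v = np.array([1.3, -0.4, 2.0])
        th = rng.uniform(0, 2 * np.pi)
        Rz = np.array([
            [np.cos(th), -np.sin(th), 0],
            [np.sin(th), np.cos(th), 0],
            [0, 0, 1],
        ])
        a = tilt_series(head_trajectory((0, 0, 0), v), HEAD_ONLY).angles[0]
        b = tilt_series(head_trajectory((0, 0, 0), Rz @ v), HEAD_ONLY).angles[0]
        assert a == pytest.approx(b, abs=1e-9)


class TestInsertionSeries:
    def _tail_traj(self, xs):
        atoms = [("PA", "LPA", 900, "L", "P", (0, 50, 0)),
                 ("PB", "LPA", 900, "L", "P", (0, 51, 0))]
        atoms += [("C%d" % (i + 1), "LPT", 901, "L", "C", (x, 0, i)) for i, x in enumerate(xs)]
        s = make_structure(atoms)
        lipid = LipidDefinition(0, 1, tails=(tuple(range(2, len(xs) + 2)),))
        return static_trajectory(s, 2), lipid

    PLANE = GatePlane(point=(0, 0, 0), normal=(1, 0, 0))

    def test_all_inward_zero_all_outward_one(self):
        traj, lipid = self._tail_traj([-1, -2, -3, -4])
        assert insertion_series(traj, lipid, self.PLANE).overall[0] == 0.0
        traj, lipid = self._tail_traj([1, 2, 3, 4])
        assert insertion_series(traj, lipid, self.PLANE).overall[0] == 1.0

    def test_half_outward(self):
        traj, lipid = self._tail_traj([1] * 12 + [-1] * 12)
        ins = insertion_series(traj, lipid, self.PLANE)
        assert ins.overall[0] == pytest.approx(0.5)

    def test_overall_is_atom_weighted_mean_of_tails(self):
        spec = SyntheticSpec(n_frames=30, fluct_sigma=0.0,
                             egress_schedule=np.random.default_rng(5).integers(
                                 0, 5, size=(30, 6)), seed=5)
        traj, truth = generate_trajectory(spec)
        ins = insertion_series(traj, truth.lipid_definition(), truth.plane())
        weighted = (ins.per_tail * ins.tail_sizes).sum(axis=1) / ins.tail_sizes.sum()
        np.testing.assert_allclose(ins.overall, weighted, atol=1e-12)

    def test_monotone_under_outward_motion(self):
        traj, lipid = self._tail_traj([-1, -2, 3, -4])
        base = insertion_series(traj, lipid, self.PLANE).overall[0]
        coords = traj.atom_template.coords
        coords[3, 0] += 10.0  # push one inward atom outward along the normal
        moved = static_trajectory(traj.atom_template.with_coords(coords), 2)
        assert insertion_series(moved, lipid, self.PLANE).overall[0] >= base


class TestEgressOrder:
    def _series(self, per_tail):
        per_tail = np.asarray(per_tail, dtype=float)
        sizes = np.full(per_tail.shape[1], 4)
        overall = per_tail.mean(axis=1)
        return InsertionSeries(overall=overall, per_tail=per_tail, tail_sizes=sizes)

    def test_prescribed_staircase(self):
        """The generator's sequential egress schedule fixes the exit order."""
        spec = SyntheticSpec(
            n_frames=60, fluct_sigma=0.0, seed=2,
            egress_schedule=np.clip(
                (np.arange(60)[:, None] - 10 * np.arange(6)[None, :]) // 2, 0, 4
            ).astype(int),
        )
        traj, truth = generate_trajectory(spec)
        ins = insertion_series(traj, truth.lipid_definition(), truth.plane())
        np.testing.assert_allclose(ins.per_tail, truth.egress_fractions, atol=1e-12)
        rep = egress_order(ins, exit_threshold=0.9)
        assert rep.order == (0, 1, 2, 3, 4, 5)
        assert rep.first_exit == (8, 18, 28, 38, 48, 58)

    def test_never_exiting_tails(self):
        rep = egress_order(self._series(np.full((20, 3), 0.5)), exit_threshold=0.9)
        assert rep.first_exit == (None, None, None)
        assert rep.order == ()

    def test_zero_threshold_exits_at_frame_zero(self):
        rep = egress_order(self._series(np.zeros((5, 4))), exit_threshold=0.0)
        assert rep.first_exit == (0, 0, 0, 0)


class TestLipidDefinition:
    def test_pa_pb_distinct(self):
        with pytest.raises(ValueError):
            LipidDefinition(1, 1, tails=((2,),))

    def test_tails_disjoint_nonempty(self):
        with pytest.raises(ValueError):
            LipidDefinition(0, 1, tails=((2, 3), (3, 4)))
        with pytest.raises(ValueError):
            LipidDefinition(0, 1, tails=((),))
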