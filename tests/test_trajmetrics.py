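import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from gatekit.collective import Trajectory
from gatekit.structio import SelectionError, StructureModel
from gatekit.toysim import gen_dihedral_trace
from gatekit.trajmetrics import (
    DOWN_RANGE,
    UP_RANGE,
    RotamerTrace,
    chi1,
    classify_rotamer,
    dihedral,
    hbond_count,
    opposite_distance,
    rmsd_timeseries,
    state_fractions,
    wrap_angle,
)


def residue_model(atom_names, coords, resname="PHE"):
    n = len(atom_names)
    return StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=np.array(atom_names),
        residue_name=np.array([resname] * n),
        residue_seq=np.full(n, 103),
        chain_id=np.array(["A"] * n),
        element=np.array([a[0] for a in atom_names]),
        coords=np.array(coords, dtype=float),
    )


class TestDihedral:
    def test_cis_is_zero(self):
        p = [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]
        assert abs(dihedral(*p)) < 1e-10

    def test_trans_is_180(self):
        p = [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]]
        assert np.isclose(dihedral(*p), 180.0)

    @pytest.mark.parametrize("angle", [-63.5, -175.5, 45.0, 120.0])
    def test_constructed_rotation_recovered(self, angle):
        """Rotate the fourth atom about the central bond by a known
        angle starting from the cis geometry."""
        p0, p1, p2 = np.array([1.0, 1, 0]), np.array([1.0, 0, 0]), np.array([2.0, 0, 0])
        axis = (p2 - p1) / np.linalg.norm(p2 - p1)
        # positive dihedral = right-hand rotation about the p1->p2 axis
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        p3 = p2 + rot.apply(np.array([0.0, 1.0, 0.0]))
        assert np.isclose(dihedral(p0, p1, p2, p3), angle, atol=1e-6)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((4, 3))
        ref = dihedral(*pts)
        R = Rotation.random(random_state=1).as_matrix()
        moved = pts @ R.T + np.array([3.0, -1.0, 2.0])
        assert np.isclose(dihedral(*moved), ref, atol=1e-8)


class TestChi1:
    def test_phe_gamma_atom_used(self):
        m = residue_model(
            ["N", "CA", "CB", "CG"],
            [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]],
        )
        assert np.isclose(chi1(m.coords, m, "A", 103), 180.0)

    def test_missing_gamma_atom_gives_nan_with_warning(self):
        m = residue_model(
            ["N", "CA", "CB"], [[1, 1, 0], [1, 0, 0], [2, 0, 0]]
        )
        with pytest.warns(UserWarning, match="missing atom"):
            assert np.isnan(chi1(m.coords, m, "A", 103))

    def test_absent_residue_raises(self):
        m = residue_model(["N", "CA", "CB", "CG"],
                          [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]])
        with pytest.raises(SelectionError):
            chi1(m.coords, m, "A", 999)


class TestClassifier:
    @pytest.mark.parametrize(
        "angle,expected",
        [(-70.0, "up"), (-180.0, "down"), (176.0, "down"),
         (-63.5, "up"), (-166.0, "down"), (-120.0, "unassigned"),
         (0.0, "unassigned"), (90.0, "unassigned")],
    )
    def test_strict_printed_ranges(self, angle, expected):
        assert classify_rotamer(angle, mode="strict") == expected

    def test_nearest_mode_never_unassigned(self):
        angles = np.linspace(-180.0, 180.0, 721)
        states = classify_rotamer(angles, mode="nearest")
        assert set(states) <= {"up", "down"}

    @given(st.floats(-360.0, 360.0))
    def test_modes_agree_inside_printed_ranges(self, angle):
        strict = classify_rotamer(angle, mode="strict")
        if strict != "unassigned":
            assert classify_rotamer(angle, mode="nearest") == strict

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_rotamer(0.0, mode="fuzzy")


class TestStateFractions:
    def _traces(self, states_per_res):
        n = len(states_per_res[0])
        return [
            RotamerTrace(
                chain="ABCD"[i], resseq=103, resname="PHE",
                times=np.arange(n, dtype=float),
                chi1=np.zeros(n),
                states=np.array(s),
            )
            for i, s in enumerate(states_per_res)
        ]

    def test_all_up_is_hundred_percent(self):
        traces = self._traces([["up"] * 5] * 4)
        df = state_fractions(traces)
        assert np.all(df["pct_up"] == 100.0)
        assert np.all(df["pct_down"] == 0.0)

    def test_three_up_one_down_is_75_25(self):
        traces = self._traces([["up"] * 3] * 3 + [["down"] * 3])
        df = state_fractions(traces)
        assert np.all(df["pct_up"] == 75.0)
        assert np.all(df["pct_down"] == 25.0)

    def test_unassigned_excluded_from_denominator(self):
        traces = self._traces(
            [["up"] * 2, ["up"] * 2, ["down"] * 2, ["unassigned"] * 2]
        )
        df = state_fractions(traces)
        assert np.allclose(df["pct_up"], 100 * 2 / 3)
        assert np.allclose(df["pct_unassigned"], 25.0)

    def test_markov_occupancy_recovered(self):
        """Classifier + fractions recover the generating chain's
        stationary occupancy within a binomial-style tolerance."""
        p_ud, p_du = 0.01, 0.03
        traces = []
        n = 10_000
        for i in range(4):
            ang, _ = gen_dihedral_trace(p_ud, p_du, n, seed=50 + i)
            traces.append(
                RotamerTrace(
                    chain="ABCD"[i], resseq=103, resname="PHE",
                    times=np.arange(n, dtype=float), chi1=ang,
                    states=classify_rotamer(ang, mode="nearest"),
                )
            )
        df = state_fractions(traces)
        expect = 100.0 * p_du / (p_ud + p_du)
        assert abs(df["pct_up"].mean() - expect) < 5.0

    def test_empty_trace_list_rejected(self):
        with pytest.raises(ValueError):
            state_fractions([])

    def test_mismatched_time_grids_rejected(self):
        t1 = self._traces([["up"] * 5])[0]
        t2 = self._traces([["up"] * 7])[0]
        with pytest.raises(ValueError, match="time grid"):
            state_fractions([t1, t2])


class TestOppositeDistance:
    def test_c4_symmetric_diagonals_equal(self, toy_system):
        spec, closed, _, _ = toy_system
        d = opposite_distance(closed.coords, closed, 2 * spec.beads_per_helix)
        assert np.isclose(d["A-C"], d["B-D"], atol=1e-9)
        assert np.isclose(d["mean"], d["A-C"])

    def test_unit_square_diagonal(self):
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float
        )
        m = StructureModel(
            serial=np.arange(1, 5),
            atom_name=np.array(["CA"] * 4),
            residue_name=np.array(["THR"] * 4),
            residue_seq=np.full(4, 112),
            chain_id=np.array(["A", "B", "C", "D"]),
            element=np.array(["C"] * 4),
            coords=coords,
        )
        d = opposite_distance(coords, m, 112)
        assert np.isclose(d["A-C"], np.sqrt(2) * 10)  # Angstrom
        assert np.isclose(d["B-D"], np.sqrt(2) * 10)

    def test_gate_distance_grows_during_opening(self, toy_system,
                                                toy_selection):
        from gatekit.collective import build_difference_ev, project
        from gatekit.eddrive import EDProtocol, run_ed
        from gatekit.structio import resolve_selection

        spec, closed, open_, energy = toy_system
        cv = build_difference_ev(closed, open_, toy_selection)
        L = project(open_.coords, cv)
        idx = resolve_selection(closed, toy_selection)
        prot = EDProtocol(cv=cv, increment=L / 600, n_steps=600, clamp_at=L)
        res = run_ed(energy, closed, prot, open_, idx, seed=1,
                     temperature=0.0, save_every=60)
        gate_res = 2 * spec.beads_per_helix
        dists = [
            opposite_distance(f, closed, gate_res)["mean"]
            for f in res.trajectory.frames
        ]
        assert np.all(np.diff(dists) > -0.05)
        assert dists[-1] > dists[0] + 5.0  # opens by > 0.5 nm

    def test_missing_residue_rejected(self, toy_system):
        _, closed, _, _ = toy_system
        with pytest.raises(SelectionError):
            opposite_distance(closed.coords, closed, 999)


class TestHBonds:
    def _coords(self, d_da, h_angle_deg):
        """Donor at origin, H along +x, acceptor at angle h_angle from
        the D->H direction at distance d_da."""
        a = np.deg2rad(h_angle_deg)
        return np.array([
            [0.0, 0.0, 0.0],                       # D
            [0.1, 0.0, 0.0],                       # H
            [d_da * np.cos(a), d_da * np.sin(a), 0.0],  # A
        ])

    def test_ideal_linear_bond_counts(self):
        assert hbond_count(self._coords(0.29, 0.0), [(0, 1)], [2]) == 1

    def test_distance_cutoff(self):
        assert hbond_count(self._coords(0.40, 0.0), [(0, 1)], [2]) == 0

    def test_angle_cutoff(self):
        assert hbond_count(self._coords(0.30, 60.0), [(0, 1)], [2]) == 0

    def test_empty_sets_warn_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert hbond_count(self._coords(0.29, 0.0), [], [2]) == 0

    def test_symmetric_under_donor_relabeling(self):
        # two equivalent donors, one acceptor each at ideal geometry
        coords = np.array([
            [0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.3, 0.0, 0.0],
            [5.0, 0.0, 0.0], [5.1, 0.0, 0.0], [5.3, 0.0, 0.0],
        ])
        donors = [(0, 1), (3, 4)]
        acceptors = [2, 5]
        n1 = hbond_count(coords, donors, acceptors)
        n2 = hbond_count(coords, donors[::-1], acceptors[::-1])
        assert n1 == n2 == 2


class TestRmsdTimeseries:
    def test_reference_frame_is_zero(self, toy_system, toy_selection):
        from gatekit.structio import resolve_selection

        _, closed, _, _ = toy_system
        idx = resolve_selection(closed, toy_selection)
        traj = Trajectory(
            frames=np.stack([closed.coords] * 3),
            times=np.arange(3, dtype=float),
        )
        series = rmsd_timeseries(traj, closed.coords, idx)
        assert np.all(series < 1e-10)

    def test_constant_trajectory_constant_series(self, toy_system,
                                                 toy_selection):
        from gatekit.structio import resolve_selection

        _, closed, open_, _ = toy_system
        idx = resolve_selection(closed, toy_selection)
        traj = Trajectory(
            frames=np.stack([open_.coords] * 4),
            times=np.arange(4, dtype=float),
        )
        series = rmsd_timeseries(traj, closed.coords, idx)
        assert np.allclose(series, series[0])
        assert series[0] > 1.0  # Angstrom

    def test_reference_shape_mismatch_rejected(self, toy_system,
                                               toy_selection):
        _, closed, _, _ = toy_system
        traj = Trajectory(
            frames=np.stack([closed.coords] * 2),
            times=np.arange(2, dtype=float),
        )
        with pytest.raises(SelectionError):
            rmsd_timeseries(traj, closed.coords[:-1], np.arange(5))


def test_wrap_angle_range_and_periodicity():
    angles = np.array([-360.0, -184.0, -180.0, 0.0, 180.0, 184.0, 541.0])
    w = wrap_angle(angles)
    assert np.all((w > -180.0) & (w <= 180.0))
    assert np.allclose(np.cos(np.deg2rad(w)), np.cos(np.deg2rad(angles)))
    assert np.allclose(np.sin(np.deg2rad(w)), np.sin(np.deg2rad(angles)))
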