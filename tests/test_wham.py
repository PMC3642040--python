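import numpy as np
import pytest

from gatekit.collective import Trajectory, build_difference_ev, project
from gatekit.structio import resolve_selection
from gatekit.toysim import AnalyticLandscape, run_bd, sample_biased_1d
from gatekit.wham import (
    PMFProfile,
    UmbrellaWindow,
    WHAMConvergenceError,
    bootstrap_pmf,
    make_windows,
    sample_window,
    sample_window_bd,
    shade_states,
    wham,
)


def flat_landscape(lo=-5.0, hi=5.0):
    return AnalyticLandscape(centers=[0.0], depths=[0.0], widths=[1.0],
                             bounds=(lo, hi), wall_k=80.0)


def window_set(landscape, centers, k, n=4000, seed0=0):
    return [
        sample_window(landscape, c, k, n_samples=n, seed=seed0 + i)
        for i, c in enumerate(centers)
    ]


class TestWindowTypes:
    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            UmbrellaWindow(center=0.0, force_constant=1.0, samples=[])

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, force_constant=-1.0, samples=[0.1])


class TestMakeWindows:
    def _path(self, toy_system, toy_selection):
        _, closed, open_, _ = toy_system
        cv = build_difference_ev(closed, open_, toy_selection)
        idx = cv.atom_indices
        frames = []
        for t in np.linspace(0, 1, 60):
            f = closed.coords.copy()
            f[idx] = (1 - t) * closed.coords[idx] + t * open_.coords[idx]
            frames.append(f)
        return cv, Trajectory(frames=np.array(frames),
                              times=np.arange(60, dtype=float))

    def test_39_windows_strictly_increasing(self, toy_system, toy_selection):
        cv, path = self._path(toy_system, toy_selection)
        seeds = make_windows(path, cv, n_windows=39)
        centers = [c for _, c, _ in seeds]
        assert len(seeds) == 39
        assert np.all(np.diff(centers) > 0)

    def test_force_constant_assignment(self, toy_system, toy_selection):
        cv, path = self._path(toy_system, toy_selection)
        seeds = make_windows(path, cv, n_windows=10, default_k=1.0,
                             boosted_k=100.0, boosted_set={2, 7})
        ks = [k for _, _, k in seeds]
        assert ks[2] == 100.0 and ks[7] == 100.0
        assert all(k == 1.0 for i, k in enumerate(ks) if i not in (2, 7))

    def test_all_default_when_no_boost(self, toy_system, toy_selection):
        cv, path = self._path(toy_system, toy_selection)
        seeds = make_windows(path, cv, n_windows=5)
        assert {k for _, _, k in seeds} == {1.0}

    def test_single_window_at_midpoint(self, toy_system, toy_selection):
        cv, path = self._path(toy_system, toy_selection)
        ((_, center, _),) = make_windows(path, cv, n_windows=1)
        L = project(path.frames[-1], cv)
        assert abs(center - L / 2) < L / 10

    def test_short_path_rejected(self, toy_system, toy_selection):
        cv, path = self._path(toy_system, toy_selection)
        short = Trajectory(frames=path.frames[:3], times=path.times[:3])
        with pytest.raises(ValueError, match="windows"):
            make_windows(short, cv, n_windows=10)


class TestSampleWindow:
    def test_biased_mean_at_analytic_minimum(self):
        """Harmonic landscape + harmonic bias: the biased density is a
        Gaussian at the weighted mean of the two centers."""
        k_land, k_bias = 40.0, 60.0
        land = AnalyticLandscape(centers=[0.0], depths=[0.0], widths=[1.0],
                                 bounds=(-6.0, 6.0), wall_k=k_land)
        # the landscape well is implemented by the walls here; use an
        # explicit quadratic instead for a clean closed form
        land = AnalyticLandscape(centers=[0.0], depths=[0.0], widths=[1.0],
                                 bounds=(0.0, 0.0), wall_k=k_land)
        s0 = 1.5
        w = sample_window(land, s0, k_bias, n_samples=40_000, seed=1)
        expect = k_bias * s0 / (k_land + k_bias)
        assert abs(np.mean(w.samples) - expect) < 0.02

    def test_discard_fraction_applied(self, landscape):
        w = sample_window(landscape, 1.0, 20.0, n_samples=1000,
                          discard_first_fraction=0.5, seed=0)
        assert len(w.samples) == 500
        assert w.discarded_fraction == 0.5

    def test_total_discard_rejected(self, landscape):
        with pytest.raises(ValueError):
            sample_window(landscape, 1.0, 20.0, n_samples=10,
                          discard_first_fraction=1.0, seed=0)

    def test_same_seed_identical(self, landscape):
        a = sample_window(landscape, 2.0, 15.0, n_samples=500, seed=9)
        b = sample_window(landscape, 2.0, 15.0, n_samples=500, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestWham:
    def test_flat_landscape_gives_flat_pmf(self):
        flat = flat_landscape()
        w = sample_window(flat, 0.0, 0.0, n_samples=200_000,
                          discard_first_fraction=0.5, seed=3)
        prof = wham([w], n_bins=25)
        # interior of the flat region, clear of the confining walls
        inner = prof.free_energy[np.abs(prof.bin_centers) < 4.0]
        assert np.nanmax(inner) - np.nanmin(inner) < 0.2

    def test_min_shifted_to_zero(self, landscape):
        wins = window_set(landscape, np.linspace(0.5, 11.0, 25), 25.0)
        prof = wham(wins)
        assert np.isclose(np.nanmin(prof.free_energy), 0.0)

    def test_recovers_triple_well_landscape(self, landscape):
        wins = window_set(landscape, np.linspace(0.2, 11.2, 30), 30.0,
                          n=6000)
        prof = wham(wins, n_bins=150)
        occ = np.stack([
            np.histogram(w.samples, bins=prof.bin_edges)[0] > 0
            for w in wins
        ])
        mask = (occ.sum(axis=0) >= 2) & np.isfinite(prof.free_energy)
        fe = prof.free_energy[mask] - prof.free_energy[mask].min()
        u = landscape.potential(prof.bin_centers[mask])
        rmse = np.sqrt(np.mean((fe - (u - u.min())) ** 2))
        assert rmse < 0.5

    def test_window_order_invariance(self, landscape):
        wins = window_set(landscape, np.linspace(1.0, 10.0, 12), 25.0)
        prof1 = wham(wins, n_bins=80)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(wins)))
        prof2 = wham([wins[i] for i in perm], n_bins=80,
                     bin_edges=prof1.bin_edges)
        assert np.allclose(prof1.free_energy, prof2.free_energy,
                           atol=1e-6, equal_nan=True)

    def test_two_identical_windows_equal_one_with_doubled_samples(
        self, landscape
    ):
        w = sample_window(landscape, 5.0, 20.0, n_samples=4000, seed=4)
        double = UmbrellaWindow(
            center=5.0, force_constant=20.0,
            samples=np.concatenate([w.samples, w.samples]),
        )
        prof1 = wham([w, w], n_bins=60)
        prof2 = wham([double], n_bins=60, bin_edges=prof1.bin_edges)
        assert np.allclose(prof1.free_energy, prof2.free_energy,
                           atol=1e-8, equal_nan=True)

    def test_overlap_gap_warns_and_leaves_nan(self, landscape):
        w1 = sample_window(landscape, 1.0, 200.0, n_samples=2000, seed=1)
        w2 = sample_window(landscape, 10.0, 200.0, n_samples=2000, seed=2)
        with pytest.warns(UserWarning, match="overlap"):
            prof = wham([w1, w2], n_bins=100)
        assert np.any(~np.isfinite(prof.free_energy))

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            wham([])


class TestBootstrap:
    def test_zero_bootstraps_warn_empty(self, landscape):
        wins = window_set(landscape, [1.0, 2.0], 25.0, n=500)
        with pytest.warns(UserWarning, match="n_boot"):
            se = bootstrap_pmf(wins, n_boot=0)
        assert len(se) == 0

    def test_same_seed_identical_se(self, landscape):
        wins = window_set(landscape, np.linspace(0.5, 3.0, 6), 25.0, n=1500)
        se1 = bootstrap_pmf(wins, n_boot=8, seed=5)
        se2 = bootstrap_pmf(wins, n_boot=8, seed=5)
        assert np.allclose(se1, se2, equal_nan=True)

    def test_more_samples_shrink_errors(self, landscape):
        centers = np.linspace(0.5, 3.0, 6)
        small = window_set(landscape, centers, 25.0, n=800, seed0=10)
        big = window_set(landscape, centers, 25.0, n=6400, seed0=20)
        prof = wham(small, n_bins=60)
        se_small = bootstrap_pmf(small, n_boot=20, seed=1,
                                 bin_edges=prof.bin_edges)
        se_big = bootstrap_pmf(big, n_boot=20, seed=1,
                               bin_edges=prof.bin_edges)
        assert np.nanmedian(se_big) < np.nanmedian(se_small)


class TestToyWindows:
    def test_bd_window_samples_near_center(self, toy_system, toy_selection):
        _, closed, open_, energy = toy_system
        cv = build_difference_ev(closed, open_, toy_selection)
        w = sample_window_bd(
            energy, cv, closed.coords, 0.0, 2000.0, n_steps=1500, seed=2
        )
        assert abs(np.mean(w.samples)) < 0.1
        assert w.source == "bd"


class TestShadeStates:
    def test_state_intervals_and_disjointness(self, toy_system,
                                              toy_selection):
        _, closed, open_, energy = toy_system
        cv = build_difference_ev(closed, open_, toy_selection)
        trc = run_bd(energy, closed.coords, 800, seed=11, save_every=20)
        tro = run_bd(energy, open_.coords, 800, seed=12, save_every=20)
        sh = shade_states(None, {"closed": trc, "open": tro}, cv)
        assert sh["closed"]["min"] <= 0.0 <= sh["closed"]["max"]
        assert sh["closed"]["max"] < sh["open"]["min"]  # disjoint

    def test_empty_trajectory_rejected(self, toy_system, toy_selection):
        _, closed, open_, _ = toy_system
        cv = build_difference_ev(closed, open_, toy_selection)
        empty = Trajectory(
            frames=np.empty((0, closed.n_atoms, 3)), times=np.empty(0)
        )
        with pytest.raises(ValueError, match="empty"):
            shade_states(None, {"closed": empty}, cv)
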