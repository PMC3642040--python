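"""Umbrella sampling along the gating coordinate and a self-contained
WHAM solver with bootstrap errors.

Umbrella windows restrain the scalar projection s onto the collective
vector with a harmonic bias k/2 (s - s0)^2. The weighted-histogram
analysis method then removes the biases self-consistently:

    p(b) = sum_i h_i(b) / sum_i N_i exp(-beta (w_i(b) - f_i))
    exp(-beta f_i) = sum_b c_i(b) p(b)

iterated until the window free-energy constants f_i stabilise; the
potential of mean force is F(b) = -kT ln p(b), shifted so its minimum
is zero. Errors come from whole-window bootstrap resampling (each
window's samples redrawn with replacement, WHAM re-solved, replicate
profiles aligned at their minima before taking the per-bin SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .collective import CollectiveVector, Trajectory, project
from .toysim import AnalyticLandscape, sample_biased_1d

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "make_windows",
    "sample_window",
    "wham",
    "bootstrap_pmf",
    "shade_states",
    "WHAMConvergenceError",
]


class WHAMConvergenceError(RuntimeError):
    pass


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate for one window."""

    center: float                  # s0, nm
    force_constant: float          # kJ mol^-1 nm^-2
    samples: np.ndarray            # projections (nm), post-discard
    discarded_fraction: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if len(self.samples) == 0:
            raise ValueError("window has no samples after discard")


@dataclass
class PMFProfile:
    """Free-energy curve (kJ/mol) on bin centers, minimum at zero."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    bootstrap_se: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    n_iterations: int = 0
    residual: float = np.nan
    bin_edges: np.ndarray | None = None

    def covered(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def make_windows(
    path_traj: Trajectory,
    cv: CollectiveVector,
    n_windows: int = 39,
    default_k: float = 1.0,
    boosted_k: float = 100.0,
    boosted_set: set[int] | None = None,
):
    """Pick window seed frames at ~equal spacing along the coordinate.

    The standard protocol uses 39 windows along the driven path, most
    at a soft force constant with a boosted subset bridging the
    barriers; ``boosted_set`` holds the indices (0-based, in center
    order) of the boosted windows. Returns a list of
    (seed_coords, center, force_constant).
    """
    if path_traj.n_frames < n_windows:
        raise ValueError(
            f"path has {path_traj.n_frames} frames < {n_windows} windows"
        )
    boosted_set = boosted_set or set()
    proj = np.array([project(f, cv) for f in path_traj.frames])
    if n_windows == 1:
        centers = np.array([0.5 * (proj.min() + proj.max())])
    else:
        centers = np.linspace(proj.min(), proj.max(), n_windows)
    out = []
    for w, c in enumerate(centers):
        i = int(np.argmin(np.abs(proj - c)))
        k = boosted_k if w in boosted_set else default_k
        out.append((path_traj.frames[i].copy(), float(proj[i]), float(k)))
    return out


def sample_window(
    system,
    center: float,
    force_constant: float,
    n_samples: int = 10000,
    discard_first_fraction: float = 0.5,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    source: str = "",
) -> UmbrellaWindow:
    """Draw biased samples of the coordinate for one window.

    ``system`` is an :class:`AnalyticLandscape` (exact rejection
    sampling of the biased density — the oracle path used for WHAM
    validation). Half of the draw is discarded by default, mirroring
    the equilibration discard of time-series umbrella runs (50 of
    100 ns per window in the reference protocol); for i.i.d. draws
    this only reduces the sample count but keeps the contract uniform.
    """
    if not 0.0 <= discard_first_fraction < 1.0:
        raise ValueError("discard fraction must be in [0, 1)")
    if not isinstance(system, AnalyticLandscape):
        raise TypeError(
            "sample_window draws from an AnalyticLandscape; use "
            "sample_window_bd for a dynamical system"
        )
    raw = sample_biased_1d(
        system, center, force_constant, n_samples,
        temperature=temperature, seed=seed,
    )
    n_discard = int(len(raw) * discard_first_fraction)
    kept = raw[n_discard:]
    if len(kept) == 0:
        raise ValueError("no samples left after discard")
    return UmbrellaWindow(
        center=center,
        force_constant=force_constant,
        samples=kept,
        discarded_fraction=discard_first_fraction,
        source=source or "landscape",
    )


class _BiasedProjectionEnergy:
    """System energy plus k/2 (s(x) - s0)^2 on the projection; the
    bias force follows by the chain rule through the fitted projection
    (the rotation's own derivative is neglected, the standard
    small-correction approximation for collective-variable biases)."""

    def __init__(self, base, cv: CollectiveVector, center: float, k: float):
        self.base = base
        self.cv = cv
        self.center = center
        self.k = k
        self._d3 = cv.direction.reshape(-1, 3)

    def value(self, x):
        s = project(x, self.cv)
        return self.base.value(x) + 0.5 * self.k * (s - self.center) ** 2

    def gradient(self, x):
        from .collective import kabsch_fit

        g = self.base.gradient(x).copy()
        sel = x[self.cv.atom_indices]
        rot, _, fitted = kabsch_fit(
            sel, self.cv.reference_coords, self.cv._fit_positions()
        )
        s = float(
            self.cv.direction @ (fitted - self.cv.reference_coords).ravel()
        )
        g[self.cv.atom_indices] += (
            self.k * (s - self.center) * self._d3 @ rot
        )
        return g


def sample_window_bd(
    energy,
    cv: CollectiveVector,
    seed_coords: np.ndarray,
    center: float,
    force_constant: float,
    n_steps: int = 20000,
    discard_first_fraction: float = 0.5,
    dt: float = 0.002,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 50.0,
    seed: int = 0,
    save_every: int = 10,
) -> UmbrellaWindow:
    """Umbrella window on a dynamical system: Brownian dynamics under
    the harmonic projection bias, first fraction discarded."""
    from .toysim import run_bd

    biased = _BiasedProjectionEnergy(energy, cv, center, force_constant)
    traj = run_bd(
        biased, seed_coords, n_steps, dt=dt, temperature=temperature,
        friction=friction, seed=seed, save_every=save_every,
    )
    proj = np.array([project(f, cv) for f in traj.frames])
    n_discard = int(len(proj) * discard_first_fraction)
    kept = proj[n_discard:]
    if len(kept) == 0:
        raise ValueError("no samples left after discard")
    return UmbrellaWindow(
        center=center, force_constant=force_constant, samples=kept,
        discarded_fraction=discard_first_fraction, source="bd",
    )


def _overlap_report(windows, edges) -> list[tuple[int, int]]:
    """Adjacent window pairs (by center order) with no shared bin."""
    order = np.argsort([w.center for w in windows])
    gaps = []
    occ = [
        np.histogram(windows[i].samples, bins=edges)[0] > 0 for i in order
    ]
    for a, b in zip(range(len(order) - 1), range(1, len(order))):
        if not np.any(occ[a] & occ[b]):
            gaps.append((int(order[a]), int(order[b])))
    return gaps


def wham(
    windows: list[UmbrellaWindow],
    n_bins: int = 200,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-7,
    max_iter: int = 100000,
    bin_edges: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM over the pooled window histograms.

    Iterates the window constants f_i until max |delta f| < ``tol``
    (kJ/mol). Bins never visited by any window get NaN free energy; a
    warning reports adjacent windows without histogram overlap.
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    kbt = kt(temperature)
    beta = 1.0 / kbt
    if bin_edges is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        span = max(hi - lo, 1e-12)
        bin_edges = np.linspace(lo - 1e-9 * span, hi + 1e-9 * span,
                                n_bins + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    gaps = _overlap_report(windows, bin_edges)
    if gaps:
        warnings.warn(
            f"umbrella histograms have overlap gaps between window pairs "
            f"{gaps}; PMF will be disconnected there",
            stacklevel=2,
        )
    h = np.stack(
        [np.histogram(w.samples, bins=bin_edges)[0] for w in windows]
    ).astype(float)                                   # (n_win, n_bins)
    n_tot = h.sum(axis=1)                             # N_i
    pooled = h.sum(axis=0)                            # (n_bins,)
    bias = np.stack(
        [0.5 * w.force_constant * (centers - w.center) ** 2
         for w in windows]
    )                                                 # w_i(b), kJ/mol
    c = np.exp(-beta * bias)
    f = np.zeros(len(windows))                        # f_i, kJ/mol
    visited = pooled > 0
    for it in range(1, max_iter + 1):
        denom = (n_tot * np.exp(beta * f)) @ c        # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(visited & (denom > 0), pooled / denom, 0.0)
        z = c @ p                                     # exp(-beta f_new)
        f_new = -kbt * np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]                             # gauge: f_0 = 0
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            break
    else:
        raise WHAMConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} kJ/mol)"
        )
    # normalise within bin widths and convert to free energy
    widths = np.diff(bin_edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = p / widths
    fe = np.full(len(centers), np.nan)
    ok = visited & (dens > 0)
    fe[ok] = -kbt * np.log(dens[ok])
    if np.any(ok):
        fe -= np.nanmin(fe)
    return PMFProfile(
        bin_centers=centers,
        free_energy=fe,
        temperature=temperature,
        n_iterations=it,
        residual=resid,
        bin_edges=bin_edges,
    )


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    n_boot: int = 50,
    seed: int = 0,
    n_bins: int = 200,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-7,
    max_iter: int = 100000,
    bin_edges: np.ndarray | None = None,
) -> np.ndarray:
    """Whole-window bootstrap standard error per PMF bin.

    Each replicate redraws every window's samples with replacement,
    re-solves WHAM on the shared bin grid, aligns the replicate at its
    minimum (WHAM fixes only relative free energies) and the SE is the
    per-bin standard deviation over replicates. Failed replicates are
    counted and reported via a warning.
    """
    if n_boot == 0:
        warnings.warn("n_boot = 0: returning empty SE vector", stacklevel=2)
        return np.empty(0)
    if bin_edges is None:
        full = wham(windows, n_bins=n_bins, temperature=temperature,
                    tol=tol, max_iter=max_iter)
        bin_edges = full.bin_edges
    rng = np.random.default_rng(seed)
    reps = []
    failures = 0
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            pick = rng.integers(0, len(w.samples), len(w.samples))
            resampled.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    samples=w.samples[pick],
                    discarded_fraction=w.discarded_fraction,
                    source=w.source,
                )
            )
        try:
            prof = wham(resampled, temperature=temperature, tol=tol,
                        max_iter=max_iter, bin_edges=bin_edges)
            reps.append(prof.free_energy)
        except WHAMConvergenceError:
            failures += 1
    if failures:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap replicates failed to converge",
            stacklevel=2,
        )
    if not reps:
        raise WHAMConvergenceError("all bootstrap replicates failed")
    arr = np.stack(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(arr, axis=0, ddof=1 if len(reps) > 1 else 0)
    return se


def shade_states(
    pmf: PMFProfile,
    state_trajs: dict[str, Trajectory],
    cv: CollectiveVector,
) -> dict[str, dict[str, float]]:
    """Projection intervals of state ensembles along the coordinate.

    For each named trajectory (closed / intermediate / open ensembles)
    returns min, max and the 5-95% quantiles of the projections — the
    shaded sampling regions along the profile — plus the free energy
    at the interval midpoint when covered, to report whether the state
    sits inside a well.
    """
    out: dict[str, dict[str, float]] = {}
    for name, traj in state_trajs.items():
        if traj.n_frames == 0:
            raise ValueError(f"state trajectory {name!r} is empty")
        proj = np.array([project(f, cv) for f in traj.frames])
        mid = float(np.median(proj))
        entry = {
            "min": float(proj.min()),
            "max": float(proj.max()),
            "q05": float(np.quantile(proj, 0.05)),
            "q95": float(np.quantile(proj, 0.95)),
            "median": mid,
        }
        if pmf is not None:
            i = int(np.argmin(np.abs(pmf.bin_centers - mid)))
            entry["free_energy_at_median"] = float(pmf.free_energy[i])
        out[name] = entry
    return out
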