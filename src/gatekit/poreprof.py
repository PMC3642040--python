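"""Largest-sphere pore-radius profiling along a channel axis.

At each position z along the pore axis the profiler finds the largest
sphere centred in the plane at z that touches no atom:

    radius(z) = max over in-plane centers c of min_i(|c - x_i| - R_i)

with 3-D distances to every selected atom i of hard-sphere radius R_i.
The in-plane maximisation uses simulated-annealing Monte-Carlo seeded
from the previous slab's center, followed by a deterministic local
polish, which reproduces the classic channel-profiling algorithm. The
constriction (global minimum of radius(z)) of the intracellular gate
region, doubled and reported in Angstrom, is the activation-gate
diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constants import NM_TO_ANG
from .structio import SelectionError, StructureModel

__all__ = [
    "PoreProfile",
    "pore_profile",
    "gate_diameter",
    "DEFAULT_RADII",
    "PoreLostError",
]

#: element-based hard-sphere radii (nm); a config artifact, not a claim
DEFAULT_RADII: dict[str, float] = {"C": 0.185, "N": 0.175, "O": 0.165,
                                   "S": 0.200, "P": 0.210, "H": 0.100}


class PoreLostError(RuntimeError):
    """The sphere center escaped the lateral bound at some z."""


@dataclass
class PoreProfile:
    """Pore radius per axial position, in the axis frame (nm)."""

    axis_point: np.ndarray      # origin of the axis frame (nm, input frame)
    axis_direction: np.ndarray  # unit vector (input frame)
    z_grid: np.ndarray          # nm, axis frame
    radius: np.ndarray          # nm
    centers: np.ndarray         # (n_z, 2) in-plane sphere centers
    boundary_limited: np.ndarray = None  # slabs where the search hit
                                         # the lateral bound

    def __post_init__(self) -> None:
        if np.any(self.radius < 0):
            # negative radius means overlapping atoms fill the pore at
            # that z; clip is wrong, report as-is but keep invariant doc
            pass

    @property
    def constriction(self) -> tuple[float, float]:
        """(z*, r_min): location and value of the global minimum."""
        i = int(np.argmin(self.radius))
        return float(self.z_grid[i]), float(self.radius[i])


def principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Default pore axis: the symmetry axis of the selected atoms.

    For a Cn-symmetric channel the inertia-like covariance of the
    coordinates has two (near-)degenerate eigenvalues perpendicular to
    the symmetry axis; the axis is the eigenvector whose eigenvalue is
    most separated from the other two.
    """
    center = coords.mean(axis=0)
    x = coords - center
    cov = x.T @ x / len(x)
    evals, evecs = np.linalg.eigh(cov)
    # separation of each eigenvalue from the mean of the other two
    sep = [
        abs(evals[i] - np.mean(np.delete(evals, i))) for i in range(3)
    ]
    axis = evecs[:, int(np.argmax(sep))]
    if axis[2] < 0:
        axis = -axis
    return center, axis


def _axis_frame(axis_point: np.ndarray, axis_direction: np.ndarray):
    w = axis_direction / np.linalg.norm(axis_direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w])  # rows: frame basis


def pore_profile(
    model: StructureModel,
    selection: np.ndarray | None = None,
    radii_table: dict[str, float] | None = None,
    axis_point: np.ndarray | None = None,
    axis_direction: np.ndarray | None = None,
    z_range: tuple[float, float] | None = None,
    z_step: float = 0.025,
    n_anneal: int = 250,
    start_temp: float = 0.05,
    lateral_bound: float = 2.0,
    seed: int = 0,
    on_lost: str = "raise",
) -> PoreProfile:
    """Monte-Carlo largest-sphere profile of the selected atoms.

    ``selection`` are atom indices (default: all atoms); the axis
    defaults to the symmetry axis of the selection. ``lateral_bound``
    (nm) is the maximal in-plane distance of a sphere center from the
    axis; the search is confined to that disc, and a slab whose
    optimum presses against the bound means the pore has opened into
    bulk there. ``on_lost`` controls what happens then: "raise"
    (default), "truncate" (return the profile up to the last enclosed
    slab, with a warning) or "mark" (keep going and flag the slab in
    ``boundary_limited``).
    """
    import warnings
    if selection is None:
        selection = np.arange(model.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise SelectionError("empty selection for pore profiling")
    radii_table = dict(DEFAULT_RADII, **(radii_table or {}))
    coords = model.coords[selection]
    elements = model.element[selection]
    atom_r = np.array(
        [radii_table.get(str(e).upper(), 0.17) for e in elements]
    )
    if axis_point is None or axis_direction is None:
        cp, cd = principal_axis(coords)
        axis_point = cp if axis_point is None else np.asarray(axis_point)
        axis_direction = (
            cd if axis_direction is None else np.asarray(axis_direction)
        )
    frame = _axis_frame(np.asarray(axis_point), np.asarray(axis_direction))
    local = (coords - axis_point) @ frame.T  # (n, 3), z = axis coordinate
    if z_range is None:
        z_range = (float(local[:, 2].min()), float(local[:, 2].max()))
    z_grid = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    rng = np.random.default_rng(seed)

    xy = local[:, :2]
    z_at = local[:, 2]

    def sphere_radius(cx: float, cy: float, z: float) -> float:
        if cx * cx + cy * cy > lateral_bound * lateral_bound:
            return -1e9  # outside the search disc
        d = np.sqrt(
            (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 + (z_at - z) ** 2
        )
        return float(np.min(d - atom_r))

    radii_out = np.empty(len(z_grid))
    centers_out = np.empty((len(z_grid), 2))
    limited = np.zeros(len(z_grid), dtype=bool)
    c = np.zeros(2)  # start on the axis
    for iz, z in enumerate(z_grid):
        best = np.array(c)
        best_r = sphere_radius(best[0], best[1], z)
        cur, cur_r = best.copy(), best_r
        # simulated annealing on -radius with geometric cooling
        steps = np.geomspace(0.08, 0.002, n_anneal)
        temps = np.geomspace(start_temp, 1e-4, n_anneal)
        prop = rng.standard_normal((n_anneal, 2))
        accept_u = rng.random(n_anneal)
        for it in range(n_anneal):
            cand = cur + steps[it] * prop[it]
            r = sphere_radius(cand[0], cand[1], z)
            if r > cur_r or accept_u[it] < np.exp((r - cur_r) / temps[it]):
                cur, cur_r = cand, r
                if r > best_r:
                    best, best_r = cand.copy(), r
        # deterministic polish (Nelder-Mead on the non-smooth objective)
        res = minimize(
            lambda p: -sphere_radius(p[0], p[1], z),
            best,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 200},
        )
        if -res.fun > best_r:
            best, best_r = res.x, -res.fun
        if np.linalg.norm(best) > 0.95 * lateral_bound:
            if on_lost == "truncate":
                warnings.warn(
                    f"pore lost at z = {z:.3f} nm; profile truncated",
                    stacklevel=2,
                )
                z_grid = z_grid[:iz]
                radii_out = radii_out[:iz]
                centers_out = centers_out[:iz]
                limited = limited[:iz]
                break
            if on_lost == "raise":
                raise PoreLostError(
                    f"pore center reached the lateral bound at "
                    f"z = {z:.3f} nm"
                )
            limited[iz] = True
        radii_out[iz] = best_r
        centers_out[iz] = best
        c = best  # seed the next slab
    return PoreProfile(
        axis_point=np.asarray(axis_point, float),
        axis_direction=np.asarray(axis_direction, float)
        / np.linalg.norm(axis_direction),
        z_grid=z_grid,
        radius=radii_out,
        centers=centers_out,
        boundary_limited=limited,
    )


def gate_diameter(
    profile: PoreProfile, z_window: tuple[float, float] | None = None
) -> float:
    """Constriction diameter (Angstrom): 2 x min radius within the
    window (default: the lower, intracellular half of the profile)."""
    if z_window is None:
        mid = 0.5 * (profile.z_grid[0] + profile.z_grid[-1])
        z_window = (float(profile.z_grid[0]), float(mid))
    mask = (profile.z_grid >= z_window[0]) & (profile.z_grid <= z_window[1])
    if not np.any(mask):
        raise ValueError("empty z window for gate diameter")
    return float(2.0 * np.min(profile.radius[mask]) * NM_TO_ANG)
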