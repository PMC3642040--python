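"""Synthetic systems: a coarse-grained tetrameric channel, Brownian
dynamics, analytic 1-D landscapes and two-state dihedral traces.

These generators define the desk-scale study conditions for the gating
machinery:

* :func:`make_toy_channel` builds a four-subunit bead channel with
  distinct closed/open endpoint geometries (TM2 C-terminal beads splayed
  outward when open) and a dual-basin elastic-network energy. The two
  endpoint elastic networks are blended by a smooth soft-minimum, with a
  bias making the closed basin deeper, and the inter-subunit springs
  couple the subunits so that driving fewer than three of them is
  resisted by the rest.
* :func:`run_bd` propagates overdamped Langevin (Euler-Maruyama)
  dynamics; its long-time samples are Boltzmann-distributed, which is
  all the gating tests need (no inertial realism is attempted).
* :class:`AnalyticLandscape` provides 1-D triple-well potentials with an
  exactly known Boltzmann density: the ground truth for WHAM recovery.
* :func:`gen_dihedral_trace` emits two-state Markov chi1 traces with the
  up/down basins used by the rotamer classifier.
* :func:`synthetic_kcsa` builds *synthetic* stand-in backbone tetramers
  for the closed/intermediate/open channel states (the deposited crystal
  structures are not redistributable here); their TM2 bundle geometry is
  self-calibrated so the activation-gate diameters and the closed/open
  backbone RMSD match the published channel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .structio import SelectionSpec, StructureModel
from .collective import Trajectory

__all__ = [
    "ToyChannelSpec",
    "CooperativeChannelEnergy",
    "make_toy_channel",
    "toy_selection_spec",
    "gate_radius",
    "run_bd",
    "run_bd_1d",
    "sequential_opening_path",
    "AnalyticLandscape",
    "default_landscape",
    "sample_biased_1d",
    "gen_dihedral_trace",
    "synthetic_kcsa",
    "BDDivergenceError",
    "EnvelopeError",
]


class BDDivergenceError(RuntimeError):
    """Coordinates blew up; suggests a smaller time step."""


class EnvelopeError(RuntimeError):
    """Rejection-sampling envelope was exceeded or support escaped grid."""


def _wrap_angle(a):
    """Wrap degrees to (-180, 180]."""
    w = -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)
    return w


# ---------------------------------------------------------------------------
# Toy tetrameric channel
# ---------------------------------------------------------------------------

@dataclass
class ToyChannelSpec:
    """Geometry, springs and thermodynamics of the toy channel.

    The defaults are the package's standard study conditions: a
    C4-symmetric tetramer, two bead helices per subunit (TM1 static,
    TM2 mobile), a closed gate radius smaller than the open one, and a
    closed basin deeper than the open one by ``double_well_bias``.
    """

    n_subunits: int = 4
    beads_per_helix: int = 6
    tm1_radius: float = 1.5          # nm, static outer helix
    tm2_top_radius: float = 1.0      # nm, TM2 radial position at the top
    tm2_bottom_closed: float = 0.35  # nm, gate bead radius when closed
    tm2_bottom_open: float = 1.35    # nm, gate bead radius when open
    z_span: float = 1.5              # nm, vertical extent of the helices
    k_intra: float = 800.0           # kJ mol^-1 nm^-2
    k_inter: float = 400.0           # kJ mol^-1 nm^-2
    enm_cutoff: float = 2.0          # nm, contact cutoff for springs
    double_well_bias: float = 40.0   # kJ/mol penalty on the open basin
    barrier_height: float = 500.0    # kJ/mol quartic openness barrier (B)
    coupling_j: float = 85.0         # kJ/mol ferroelastic neighbour coupling
    registration_k: float = 150.0    # kJ/mol azimuthal gate registration
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 50.0           # ps^-1
    seed: int = 0


#: chain ids used for subunits
_CHAIN_IDS = "ABCDEFGH"

#: toy residue numbering: TM1 beads 1..m, TM2 beads m+1..2m
def toy_selection_spec(
    beads_per_helix: int = 6, chains=None, include_loops: bool = False
) -> SelectionSpec:
    m = beads_per_helix
    return SelectionSpec(
        segment_ranges={"TM1": (1, m), "TM2": (m + 1, 2 * m)},
        backbone_atom_names=frozenset({"CA"}),
        include_loops=include_loops,
        chains=tuple(chains) if chains is not None else None,
    )


def _toy_coords(spec: ToyChannelSpec, open_state: bool) -> np.ndarray:
    m = spec.beads_per_helix
    zs = np.linspace(spec.z_span / 2, -spec.z_span / 2, m)
    frac = np.linspace(0.0, 1.0, m)
    r_bot = spec.tm2_bottom_open if open_state else spec.tm2_bottom_closed
    tm2_r = spec.tm2_top_radius + (r_bot - spec.tm2_top_radius) * frac
    coords = []
    for u in range(spec.n_subunits):
        phi = 2 * np.pi * u / spec.n_subunits
        phi1 = phi + np.deg2rad(20.0)  # TM1 azimuthal offset
        for z in zs:  # TM1, identical in both endpoints
            coords.append(
                [spec.tm1_radius * np.cos(phi1),
                 spec.tm1_radius * np.sin(phi1), z]
            )
        for r, z in zip(tm2_r, zs):  # TM2, splays outward when open
            coords.append([r * np.cos(phi), r * np.sin(phi), z])
    return np.array(coords)


def _toy_model(spec: ToyChannelSpec, coords: np.ndarray) -> StructureModel:
    m = spec.beads_per_helix
    n_per = 2 * m
    serial, names, resnames, resseq, chains, elements = [], [], [], [], [], []
    for u in range(spec.n_subunits):
        for j in range(n_per):
            serial.append(u * n_per + j + 1)
            names.append("CA")
            resnames.append("ALA")
            resseq.append(j + 1)
            chains.append(_CHAIN_IDS[u])
            elements.append("C")
    return StructureModel(
        serial=np.array(serial),
        atom_name=np.array(names, dtype="U6"),
        residue_name=np.array(resnames, dtype="U5"),
        residue_seq=np.array(resseq),
        chain_id=np.array(chains, dtype="U4"),
        element=np.array(elements, dtype="U2"),
        coords=coords,
    )


class CooperativeChannelEnergy:
    """Dual-basin morphing elastic network with cooperative subunits.

    Each subunit u carries a geometric openness order parameter

        o_u = (r_u - r_closed) / (r_open - r_closed)

    where r_u is the in-plane distance of its TM2 C-terminal (gate)
    bead from the channel center (the mean bead position). The
    subunit's elastic network morphs its rest lengths between the
    closed and open endpoint geometry with a smoothstep of o_u, so the
    chain is held stiffly (spring constant ``k_intra``) around the
    interpolated geometry at every stage of opening; inter-subunit
    contacts (adjacent chains only) morph with the mean openness of
    the two chains involved. On top of the elastic terms each subunit
    feels a bistable quartic potential B o^2 (1-o)^2 (wells at closed
    and open, barrier B/16 between), a per-subunit bias
    ``double_well_bias / n_subunits`` that makes the fully closed
    channel the global minimum, and a ferroelastic coupling
    J (o_u - o_v)^2 to each ring neighbour. The coupling-to-barrier
    ratio is chosen so that a free subunit flips open only when *both*
    its neighbours are open: driving one or two subunits leaves the
    rest closed, driving three opens the fourth — the cooperativity
    signature probed by the essential-dynamics scans.
    """

    def __init__(self, closed: np.ndarray, open_: np.ndarray,
                 chain_index: np.ndarray, spec: ToyChannelSpec):
        self.spec = spec
        self.n_subunits = int(chain_index.max()) + 1
        self.n_atoms = len(closed)
        nc = len(closed)
        ii, jj = np.triu_indices(nc, k=1)
        dc = np.linalg.norm(closed[ii] - closed[jj], axis=1)
        do = np.linalg.norm(open_[ii] - open_[jj], axis=1)
        within = (dc <= spec.enm_cutoff) | (do <= spec.enm_cutoff)
        ci, cj = chain_index[ii], chain_index[jj]
        ring_sep = np.minimum((ci - cj) % self.n_subunits,
                              (cj - ci) % self.n_subunits)
        intra = within & (ring_sep == 0)
        # inter-subunit contacts, but only geometry-preserving ones:
        # contacts whose rest length changes a lot between endpoints
        # (the gate-bead region) would mechanically drag a neighbour
        # along during opening, which the iris-like motion of a real
        # gate avoids; openness then communicates only through the
        # explicit ferroelastic coupling. Diagonal contacts that
        # preserve geometry are kept as cross-bracing against relative
        # subunit wobble
        # bracing contacts may reach farther than the local cutoff:
        # they are harmless (geometry-preserving) and rigidify the
        # tetramer against relative subunit wobble
        brace = (dc <= 2.0 * spec.enm_cutoff) & (np.abs(do - dc) <= 0.05)
        inter = (ring_sep >= 1) & (within | brace) & (np.abs(do - dc) <= 0.05)
        self.ai, self.aj = ii[intra], jj[intra]
        self.a_dc, self.a_do = dc[intra], do[intra]
        self.a_sub = ci[intra]
        self.bi, self.bj = ii[inter], jj[inter]
        self.b_dc, self.b_do = dc[inter], do[inter]
        self.b_u, self.b_v = ci[inter], cj[inter]
        self.k_intra = spec.k_intra
        self.k_inter = spec.k_inter
        self.delta_u = spec.double_well_bias / self.n_subunits
        self.barrier = spec.barrier_height
        self.coupling = spec.coupling_j
        self.registration = spec.registration_k
        # gate beads: TM2 C-terminal bead of each chain
        n_per = 2 * spec.beads_per_helix
        self.gate_idx = np.array(
            [u * n_per + n_per - 1 for u in range(self.n_subunits)]
        )
        r_c = np.linalg.norm(
            closed[self.gate_idx, :2] - closed[:, :2].mean(axis=0), axis=1
        )
        r_o = np.linalg.norm(
            open_[self.gate_idx, :2] - open_[:, :2].mean(axis=0), axis=1
        )
        self.r_closed = float(r_c.mean())
        self.r_open = float(r_o.mean())
        # ring neighbours of each subunit
        n = self.n_subunits
        self.neigh = [((u - 1) % n, (u + 1) % n) for u in range(n)]

    # --- openness order parameter -----------------------------------------
    def openness(self, x: np.ndarray):
        """Per-subunit o_u plus the geometry needed for its gradient."""
        center = x[:, :2].mean(axis=0)
        rel = x[self.gate_idx, :2] - center
        r = np.linalg.norm(rel, axis=1)
        e = rel / np.maximum(r[:, None], 1e-12)
        o = (r - self.r_closed) / (self.r_open - self.r_closed)
        return o, e

    @staticmethod
    def _smoothstep(o):
        # identity morph, clamped to [0, 1]: the rest lengths track the
        # openness exactly, so the elastic network exerts no net force
        # on o itself (no spurious fixed points mid-transition); the
        # bistable barrier and the neighbour coupling alone shape the
        # openness dynamics
        return np.clip(o, 0.0, 1.0)

    @staticmethod
    def _smoothstep_d(o):
        o = np.asarray(o, dtype=float)
        return ((o > 0.0) & (o < 1.0)).astype(float)

    def subunit_open_weights(self, x: np.ndarray) -> np.ndarray:
        """Smoothed openness phi(o_u) of each subunit, in [0, 1]."""
        o, _ = self.openness(x)
        return self._smoothstep(o)

    def weight_open(self, x: np.ndarray) -> float:
        """Mean smoothed openness (1 = all subunits open)."""
        return float(self.subunit_open_weights(x).mean())

    def basin_energies(self, x: np.ndarray) -> tuple[float, float]:
        """Strain against the pure closed / pure open networks
        (diagnostic only; the dynamics use the morphed rest lengths)."""
        da = np.linalg.norm(x[self.ai] - x[self.aj], axis=1)
        db = np.linalg.norm(x[self.bi] - x[self.bj], axis=1)
        uc = 0.5 * self.k_intra * np.sum((da - self.a_dc) ** 2) \
            + 0.5 * self.k_inter * np.sum((db - self.b_dc) ** 2)
        uo = 0.5 * self.k_intra * np.sum((da - self.a_do) ** 2) \
            + 0.5 * self.k_inter * np.sum((db - self.b_do) ** 2)
        return float(uc), float(uo)

    #: smoothness (in o units) of the pairwise soft-minimum used for
    #: interface morphing; a closed neighbour keeps the interface at
    #: the closed rest lengths, so openness spreads only through the
    #: explicit J coupling, never through interface elasticity
    _MU = 0.15

    def _softmin_pair(self, a, b):
        m = np.minimum(a, b)
        ea = np.exp(-(a - m) / self._MU)
        eb = np.exp(-(b - m) / self._MU)
        val = m - self._MU * np.log(ea + eb) + self._MU * np.log(2.0)
        wa = ea / (ea + eb)
        return val, wa

    def _terms(self, x: np.ndarray):
        o, e = self.openness(x)
        phi = self._smoothstep(o)
        da = np.linalg.norm(x[self.ai] - x[self.aj], axis=1)
        ra = self.a_dc + (self.a_do - self.a_dc) * phi[self.a_sub]
        db = np.linalg.norm(x[self.bi] - x[self.bj], axis=1)
        omin, w_u = self._softmin_pair(o[self.b_u], o[self.b_v])
        phib = self._smoothstep(omin)
        rb = self.b_dc + (self.b_do - self.b_dc) * phib
        return o, e, phi, da, ra, db, rb, omin, w_u

    def value(self, x: np.ndarray) -> float:
        o, e, phi, da, ra, db, rb, _, _ = self._terms(x)
        u = 0.5 * self.k_intra * np.sum((da - ra) ** 2)
        u += 0.5 * self.k_inter * np.sum((db - rb) ** 2)
        u += np.sum(self.barrier * o**2 * (1 - o) ** 2)
        u += np.sum(self.delta_u * phi)
        # azimuthal registration: adjacent gate beads stay at right
        # angles about the pore axis (restrains the soft tangential
        # swing of a splayed TM2 without touching radial opening)
        for w, (a, b) in enumerate(self.neigh):
            u += 0.25 * self.registration * (
                (e[w] @ e[a]) ** 2 + (e[w] @ e[b]) ** 2
            )
        for w, (a, b) in enumerate(self.neigh):
            # pair energy J/2 (o_u - o_v)^2; the loop visits each ring
            # pair twice, hence the factor 1/4
            u += 0.25 * self.coupling * (
                (o[w] - o[a]) ** 2 + (o[w] - o[b]) ** 2
            )
        return float(u)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        o, e, phi, da, ra, db, rb, omin, w_u = self._terms(x)
        grad = np.zeros_like(x)
        g_o = np.zeros(self.n_subunits)  # dU/do_u, distributed at the end
        # intra springs around the morphing rest lengths
        d_safe = np.maximum(da, 1e-12)
        coef = self.k_intra * (da - ra) / d_safe
        f = coef[:, None] * (x[self.ai] - x[self.aj])
        np.add.at(grad, self.ai, f)
        np.add.at(grad, self.aj, -f)
        dphi = self._smoothstep_d(o)
        np.add.at(
            g_o, self.a_sub,
            -self.k_intra * (da - ra) * (self.a_do - self.a_dc)
            * dphi[self.a_sub],
        )
        # inter springs, rest length from the pair-mean openness
        d_safe = np.maximum(db, 1e-12)
        coef = self.k_inter * (db - rb) / d_safe
        f = coef[:, None] * (x[self.bi] - x[self.bj])
        np.add.at(grad, self.bi, f)
        np.add.at(grad, self.bj, -f)
        gb = (
            -self.k_inter * (db - rb) * (self.b_do - self.b_dc)
            * self._smoothstep_d(omin)
        )
        np.add.at(g_o, self.b_u, gb * w_u)
        np.add.at(g_o, self.b_v, gb * (1.0 - w_u))
        # bistable barrier, bias and ferroelastic coupling
        g_o += self.barrier * (2 * o - 6 * o**2 + 4 * o**3)
        g_o += self.delta_u * dphi
        for w, (a, b) in enumerate(self.neigh):
            g_o[w] += self.coupling * ((o[w] - o[a]) + (o[w] - o[b]))
        # chain rule: o_u depends on its gate bead and the global center
        scale = g_o / (self.r_open - self.r_closed)
        grad[self.gate_idx, :2] += scale[:, None] * e
        grad[:, :2] -= (scale[:, None] * e).sum(axis=0) / self.n_atoms
        # azimuthal registration: dW/de_u projected through the unit-
        # vector Jacobian (I - e e^T) / r
        center = x[:, :2].mean(axis=0)
        rel = x[self.gate_idx, :2] - center
        r = np.maximum(np.linalg.norm(rel, axis=1), 1e-12)
        q = np.zeros_like(e)
        for w, (a, b) in enumerate(self.neigh):
            q[w] += self.registration * (
                (e[w] @ e[a]) * e[a] + (e[w] @ e[b]) * e[b]
            )
        proj = q - e * np.sum(q * e, axis=1)[:, None]
        contrib = proj / r[:, None]
        grad[self.gate_idx, :2] += contrib
        grad[:, :2] -= contrib.sum(axis=0) / self.n_atoms
        return grad


def make_toy_channel(spec: ToyChannelSpec | None = None):
    """Build the toy channel: (closed model, open model, energy).

    Both endpoints share bead topology (chains A-D, residues 1..2m);
    the closed gate radius is smaller than the open one by
    construction.
    """
    spec = spec or ToyChannelSpec()
    if spec.tm2_bottom_closed >= spec.tm2_bottom_open:
        raise ValueError("closed gate radius must be below the open one")
    closed_xyz = _toy_coords(spec, open_state=False)
    open_xyz = _toy_coords(spec, open_state=True)
    closed = _toy_model(spec, closed_xyz)
    open_ = _toy_model(spec, open_xyz)
    n_per = 2 * spec.beads_per_helix
    chain_index = np.repeat(np.arange(spec.n_subunits), n_per)
    energy = CooperativeChannelEnergy(closed_xyz, open_xyz, chain_index, spec)
    return closed, open_, energy


def gate_radius(coords: np.ndarray, model: StructureModel,
                beads_per_helix: int = 6) -> float:
    """Gate metric: minimum opposite-bead half-distance (nm) of the
    TM2 C-terminal beads across the two diagonals."""
    bottom = 2 * beads_per_helix
    chains = model.chains()
    if len(chains) % 2:
        raise ValueError("gate metric needs an even number of subunits")
    idx = [model.find_atom(c, bottom, "CA") for c in chains]
    half = len(chains) // 2
    dists = [
        np.linalg.norm(coords[idx[u]] - coords[idx[u + half]])
        for u in range(half)
    ]
    return float(min(dists) / 2.0)


def sequential_opening_path(
    closed: StructureModel,
    open_: StructureModel,
    n_frames: int = 200,
    n_subunits: int = 4,
    beads_per_helix: int = 6,
) -> Trajectory:
    """Subunit-sequential interpolation between the endpoints.

    Frames morph one subunit at a time from the closed to the open
    geometry — the low-lying pathway of the cooperative energy, along
    which every intermediate sits in a well-defined subunit substate.
    Umbrella windows seeded from this path stay in consistent branches
    (a symmetric all-subunits-together interpolation would place every
    subunit on its bistable hilltop, and windows would fall into
    random substates, ruining the histogram chaining).
    """
    n_per = 2 * beads_per_helix
    frames = []
    for t in np.linspace(0.0, 1.0, n_frames):
        x = closed.coords.copy()
        for u in range(n_subunits):
            tu = float(np.clip(n_subunits * t - u, 0.0, 1.0))
            sl = slice(u * n_per, (u + 1) * n_per)
            x[sl] = (1 - tu) * closed.coords[sl] + tu * open_.coords[sl]
        frames.append(x)
    return Trajectory(
        frames=np.array(frames),
        times=np.arange(n_frames, dtype=float),
        model=closed,
    )


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

def run_bd(
    energy,
    start: np.ndarray,
    n_steps: int,
    dt: float = 0.002,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 50.0,
    seed: int = 0,
    save_every: int = 10,
    max_coord: float = 1e4,
) -> Trajectory:
    """Overdamped Langevin (Euler-Maruyama) propagation.

    x <- x - (dt/friction) grad U + sqrt(2 kT dt / friction) xi

    with unit reduced mass, so ``friction`` (ps^-1) sets the mobility
    scale but not the stationary distribution exp(-U/kT). At zero
    temperature this is plain gradient descent. Reproducible given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    x = np.array(start, dtype=float)
    kbt = kt(temperature)
    mob = dt / friction
    sigma = np.sqrt(2.0 * kbt * mob)
    frames = [x.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        g = energy.gradient(x)
        x = x - mob * g
        if sigma > 0:
            x = x + sigma * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > max_coord:
            raise BDDivergenceError(
                f"coordinates diverged at step {step}; use a smaller dt"
            )
        if step % save_every == 0:
            frames.append(x.copy())
            times.append(step * dt)
    return Trajectory(frames=np.array(frames), times=np.array(times))


def run_bd_1d(
    potential,
    gradient,
    s0: float,
    n_steps: int,
    dt: float = 0.01,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    seed: int = 0,
    save_every: int = 1,
) -> np.ndarray:
    """Scalar-coordinate Euler-Maruyama; returns the saved samples."""
    rng = np.random.default_rng(seed)
    kbt = kt(temperature)
    mob = dt / friction
    sigma = np.sqrt(2.0 * kbt * mob)
    s = float(s0)
    noise = rng.standard_normal(n_steps)
    out = []
    for step in range(n_steps):
        s = s - mob * float(gradient(s)) + sigma * noise[step]
        if not np.isfinite(s) or abs(s) > 1e6:
            raise BDDivergenceError(
                f"1-D coordinate diverged at step {step}; use a smaller dt"
            )
        if (step + 1) % save_every == 0:
            out.append(s)
    return np.array(out)


# ---------------------------------------------------------------------------
# Analytic landscapes
# ---------------------------------------------------------------------------

@dataclass
class AnalyticLandscape:
    """Sum of inverted Gaussians plus confining harmonic walls.

    U(s) = -sum_i depth_i exp(-(s-c_i)^2 / (2 w_i^2)) + walls

    The Boltzmann density at temperature T is known by quadrature, so
    the landscape is an exact oracle for umbrella sampling / WHAM.
    """

    centers: np.ndarray
    depths: np.ndarray
    widths: np.ndarray
    bounds: tuple[float, float] = (-1.5, 13.0)
    wall_k: float = 30.0  # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        self.centers = np.atleast_1d(np.asarray(self.centers, float))
        self.depths = np.atleast_1d(np.asarray(self.depths, float))
        self.widths = np.atleast_1d(np.asarray(self.widths, float))
        if not (len(self.centers) == len(self.depths) == len(self.widths)):
            raise ValueError("centers/depths/widths length mismatch")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")

    def potential(self, s):
        sv = np.atleast_1d(np.asarray(s, dtype=float))
        u = -np.sum(
            self.depths[:, None]
            * np.exp(-(sv[None, :] - self.centers[:, None]) ** 2
                     / (2 * self.widths[:, None] ** 2)),
            axis=0,
        )
        lo, hi = self.bounds
        u = u + 0.5 * self.wall_k * np.where(sv < lo, (sv - lo) ** 2, 0.0)
        u = u + 0.5 * self.wall_k * np.where(sv > hi, (sv - hi) ** 2, 0.0)
        return u if np.ndim(s) else float(u[0])

    def grad(self, s):
        sv = np.atleast_1d(np.asarray(s, dtype=float))
        g = np.sum(
            self.depths[:, None]
            * (sv[None, :] - self.centers[:, None])
            / self.widths[:, None] ** 2
            * np.exp(-(sv[None, :] - self.centers[:, None]) ** 2
                     / (2 * self.widths[:, None] ** 2)),
            axis=0,
        )
        lo, hi = self.bounds
        g = g + self.wall_k * np.where(sv < lo, sv - lo, 0.0)
        g = g + self.wall_k * np.where(sv > hi, sv - hi, 0.0)
        return g if np.ndim(s) else float(g[0])

    def grid(self, n: int = 4001, pad: float = 1.0) -> np.ndarray:
        lo, hi = self.bounds
        return np.linspace(lo - pad, hi + pad, n)

    def density(self, temperature: float = DEFAULT_TEMPERATURE,
                n: int = 4001):
        """Normalised Boltzmann density on a grid: (s_grid, density)."""
        s = self.grid(n)
        u = self.potential(s)
        p = np.exp(-(u - u.min()) / kt(temperature))
        z = np.trapezoid(p, s)
        return s, p / z


def default_landscape() -> AnalyticLandscape:
    """The bundled triple-well landscape for the gating coordinate.

    Three wells centered near s = 1.2, 5.4 and 10.1 nm with the closed
    (first) one deepest, separated by two barriers near s = 4 and
    s = 9 nm (the last two components are negative-depth Gaussian
    bumps that place the barrier tops). Depths are package defaults
    chosen to give clearly resolved, desk-scale barriers.
    """
    return AnalyticLandscape(
        centers=np.array([1.2, 5.4, 10.1, 4.0, 9.0]),
        depths=np.array([20.0, 14.0, 10.0, -5.0, -7.0]),
        widths=np.array([1.3, 1.0, 0.6, 0.45, 0.45]),
        bounds=(-1.5, 13.0),
    )


def sample_biased_1d(
    landscape: AnalyticLandscape,
    s0: float,
    k: float,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    grid_n: int = 8001,
) -> np.ndarray:
    """I.i.d. draws from exp(-[U(s) + k/2 (s-s0)^2]/kT) by rejection
    sampling against a piecewise-constant grid envelope."""
    if k < 0:
        raise ValueError("bias force constant must be >= 0")
    if n == 0:
        return np.array([])
    rng = np.random.default_rng(seed)
    kbt = kt(temperature)
    s = landscape.grid(grid_n, pad=2.0)
    u = landscape.potential(s) + 0.5 * k * (s - s0) ** 2
    logf = -(u - u.min()) / kbt
    # per-cell envelope: max of endpoint densities with a safety factor
    cell_log = np.maximum(logf[:-1], logf[1:]) + np.log(1.5)
    mass = np.exp(cell_log - cell_log.max()) * np.diff(s)
    if mass[0] > 1e-6 * mass.max() or mass[-1] > 1e-6 * mass.max():
        raise EnvelopeError("density leaks past grid bounds; widen the grid")
    cdf = np.cumsum(mass)
    cdf /= cdf[-1]
    out = np.empty(0)
    while len(out) < n:
        m = max(2 * (n - len(out)), 1000)
        cells = np.searchsorted(cdf, rng.random(m))
        x = s[cells] + rng.random(m) * (s[cells + 1] - s[cells])
        ulocal = landscape.potential(x) + 0.5 * k * (x - s0) ** 2
        logfx = -(ulocal - u.min()) / kbt
        if np.any(logfx > cell_log[cells] + 1e-9):
            raise EnvelopeError(
                "envelope exceeded; refine the grid (grid_n)"
            )
        accept = np.log(rng.random(m) + 1e-300) < logfx - cell_log[cells]
        out = np.concatenate([out, x[accept]])
    return out[:n]


# ---------------------------------------------------------------------------
# Two-state dihedral traces
# ---------------------------------------------------------------------------

def gen_dihedral_trace(
    p_up_to_down: float,
    p_down_to_up: float,
    n_steps: int,
    up_center: float = -63.5,
    down_center: float = -175.5,
    noise_sd: float = 8.0,
    seed: int = 0,
    start_state: str = "up",
):
    """Two-state Markov chain with wrapped-Gaussian chi1 emission.

    Returns (angles in degrees wrapped to (-180, 180], true state
    sequence as an array of 'up'/'down'), for classifier validation.
    """
    for p in (p_up_to_down, p_down_to_up):
        if not 0.0 <= p <= 1.0:
            raise ValueError("transition probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype="U4")
    s = start_state
    u = rng.random(n_steps)
    for i in range(n_steps):
        states[i] = s
        if s == "up" and u[i] < p_up_to_down:
            s = "down"
        elif s == "down" and u[i] < p_down_to_up:
            s = "up"
    centers = np.where(states == "up", up_center, down_center)
    angles = _wrap_angle(centers + noise_sd * rng.standard_normal(n_steps))
    return angles, states


# ---------------------------------------------------------------------------
# Synthetic stand-ins for the deposited channel structures
# ---------------------------------------------------------------------------

# idealised alpha-helix backbone: (radius nm, phase offset deg, z offset nm)
_HELIX_RISE = 0.15
_HELIX_TWIST = 100.0
_BB_GEOM = {
    "N": (0.157, -28.0, -0.090),
    "CA": (0.228, 0.0, 0.000),
    "C": (0.168, 27.0, 0.055),
    "O": (0.200, 24.0, 0.180),
}

_STATE_PRESETS = {
    # target activation-gate diameter (Angstrom) per channel state,
    # matching the published backbone-derived constrictions
    "closed": 5.9,
    "intermediate": 8.3,
    "open": 11.8,
}


def _helix_backbone(n_res, start_point, end_point, phase0=0.0):
    """Backbone atoms of an ideal helix along the segment start->end.

    Returns an (n_res, 4, 3) array ordered (N, CA, C, O) per residue.
    The helix is extended/compressed so n_res residues span the
    segment at the canonical rise.
    """
    start_point = np.asarray(start_point, float)
    end_point = np.asarray(end_point, float)
    axis = end_point - start_point
    length = np.linalg.norm(axis)
    axis = axis / length
    # local frame perpendicular to the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rise = length / max(n_res - 1, 1)
    out = np.empty((n_res, 4, 3))
    for i in range(n_res):
        theta0 = np.deg2rad(phase0 + i * _HELIX_TWIST)
        for a, name in enumerate(("N", "CA", "C", "O")):
            r, dphi, dz = _BB_GEOM[name]
            th = theta0 + np.deg2rad(dphi)
            out[i, a] = (
                start_point
                + (i * rise + dz * rise / _HELIX_RISE) * axis
                + r * (np.cos(th) * e1 + np.sin(th) * e2)
            )
    return out


_SYN_SEQ = {103: "PHE", 112: "THR", 113: "TRP", 114: "PHE"}


def _synthetic_chain(gate_radius_nm: float, splay_radius_nm: float,
                     phi: float, first_res: int = 22,
                     last_res: int = 124):
    """One subunit of the synthetic stand-in, rotated to azimuth phi.

    Residue layout (inclusive): N-tail 22-28, TM1 29-51, loop 52-61,
    P-helix 62-74, SF 75-79, loop 80-85, TM2 86-118, C-tail 119-124.
    TM2 runs from the extracellular top down through the bundle-
    crossing gate; ``gate_radius_nm`` sets the helix-axis distance from
    the pore axis at the gate and ``splay_radius_nm`` the outward splay
    of the C-terminal end below it.
    """
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def seg_helix(n, p0, p1, phase=0.0):
        return _helix_backbone(n, p0, p1, phase) @ rot.T

    records = []  # (resseq, name, xyz)

    def add(resseq_range, block):
        for rseq, res_atoms in zip(resseq_range, block):
            for name, xyz in zip(("N", "CA", "C", "O"), res_atoms):
                records.append((rseq, name, xyz))

    # N-tail + TM1: one continuous outer helix, intracellular -> top
    tm1 = seg_helix(30, [1.65, 0.45, -2.3], [1.45, -0.35, 2.2], phase=15.0)
    add(range(22, 52), tm1)
    # turret loop 52-61: arc near the top
    loop1 = _loop(10, tm1[-1, 2], np.array([0.95, 0.25, 2.45]) @ rot.T,
                  bulge=np.array([0.4, 0.9, 0.6]) @ rot.T)
    add(range(52, 62), loop1)
    # P-helix 62-74: short tilted helix pointing at the pore axis
    ph = seg_helix(13, [0.95, 0.25, 2.40], [0.55, 0.05, 1.15], phase=40.0)
    add(range(62, 75), ph)
    # selectivity filter 75-79: extended strand near the axis, top
    sf = _strand(5, np.array([0.45, 0.00, 1.25]) @ rot.T,
                 np.array([0.40, -0.05, 2.35]) @ rot.T)
    add(range(75, 80), sf)
    # loop 80-85 back down to TM2 top
    loop2 = _loop(6, sf[-1, 2], np.array([1.05, -0.35, 2.15]) @ rot.T,
                  bulge=np.array([1.1, -0.9, 0.3]) @ rot.T)
    add(range(80, 86), loop2)
    # TM2 + C-tail 86-124: inner helix down to the bundle-crossing
    # hinge (residue 104), then a lower segment that splays outward
    # with the channel state (closed: near-cylindrical, open: wide)
    n_upper = 19   # residues 86..104 reach the hinge
    n_lower = 20   # residues 105..124 below the hinge
    hinge_z = -1.0
    upper = seg_helix(n_upper, [1.05, -0.30, 1.9],
                      [gate_radius_nm, 0.0, hinge_z], phase=65.0)
    add(range(86, 86 + n_upper), upper)
    low = seg_helix(
        n_lower + 1, [gate_radius_nm, 0.0, hinge_z],
        [splay_radius_nm, 0.45, hinge_z - 0.15 * n_lower],
        phase=65.0 + (n_upper - 1) * _HELIX_TWIST,
    )
    add(range(86 + n_upper, 86 + n_upper + n_lower), low[1:])
    return records


def _loop(n, p0, p1, bulge):
    """Coarse loop backbone: a quadratic arc, 4 pseudo-backbone atoms
    per residue. Geometry is schematic (loops are excluded from all
    structured-segment analyses)."""
    t = np.linspace(0.0, 1.0, n)
    mid = 0.5 * (p0 + p1) + bulge
    pts = ((1 - t)[:, None] ** 2 * p0 + 2 * (t * (1 - t))[:, None] * mid
           + (t**2)[:, None] * p1)
    out = np.empty((n, 4, 3))
    offs = {"N": [-0.05, 0.0, -0.05], "CA": [0.0, 0.0, 0.0],
            "C": [0.05, 0.0, 0.05], "O": [0.05, 0.1, 0.1]}
    for i in range(n):
        for a, name in enumerate(("N", "CA", "C", "O")):
            out[i, a] = pts[i] + offs[name]
    return out


def _strand(n, p0, p1):
    """Extended-strand backbone between two points."""
    t = np.linspace(0.0, 1.0, n)
    pts = (1 - t)[:, None] * p0 + t[:, None] * p1
    perp = np.cross(p1 - p0, [0.0, 0.0, 1.0])
    nrm = np.linalg.norm(perp)
    perp = perp / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    out = np.empty((n, 4, 3))
    for i in range(n):
        flip = 1.0 if i % 2 == 0 else -1.0
        out[i, 0] = pts[i] + flip * 0.08 * perp + [0, 0, -0.05]
        out[i, 1] = pts[i]
        out[i, 2] = pts[i] - flip * 0.08 * perp + [0, 0, 0.05]
        out[i, 3] = pts[i] - flip * 0.16 * perp + [0, 0, 0.02]
    return out


def _assemble_tetramer(gate_r: float, splay_r: float) -> StructureModel:
    serial, names, resnames, resseq, chains, elements, coords = (
        [], [], [], [], [], [], []
    )
    k = 1
    for u in range(4):
        phi = np.pi / 2 * u
        for rseq, name, xyz in _synthetic_chain(gate_r, splay_r, phi):
            serial.append(k)
            k += 1
            names.append(name)
            resnames.append(_SYN_SEQ.get(rseq, "ALA"))
            resseq.append(rseq)
            chains.append(_CHAIN_IDS[u])
            elements.append(name[0])
            coords.append(xyz)
    return StructureModel(
        serial=np.array(serial),
        atom_name=np.array(names, dtype="U6"),
        residue_name=np.array(resnames, dtype="U5"),
        residue_seq=np.array(resseq),
        chain_id=np.array(chains, dtype="U4"),
        element=np.array(elements, dtype="U2"),
        coords=np.array(coords),
    )


def enumerated_gate_diameter(
    model: StructureModel,
    radii: dict[str, float],
    z_window: tuple[float, float] = (-3.2, -0.6),
    n_z: int = 261,
) -> float:
    """On-axis gate diameter (Angstrom) by direct enumeration.

    For a C4-symmetric model the largest sphere at each z sits on the
    symmetry axis, so the radius is min_i(|x_i - (0,0,z)| - R_i)
    evaluated over all atoms; the gate diameter is twice the minimum
    over the window. Serves as the independent geometric oracle for
    the Monte-Carlo pore profiler.
    """
    xy = model.coords[:, :2]
    z = model.coords[:, 2]
    r_at = np.array([radii.get(e, 0.17) for e in model.element])
    zs = np.linspace(z_window[0], z_window[1], n_z)
    d_xy2 = np.sum(xy**2, axis=1)
    best = np.inf
    for zz in zs:
        r = np.min(np.sqrt(d_xy2 + (z - zz) ** 2) - r_at)
        best = min(best, r)
    return 2.0 * best * 10.0


_DEFAULT_RADII = {"C": 0.185, "N": 0.175, "O": 0.165}

# calibration targets for the synthetic stand-ins
_RMSD_TARGET_NM = 0.40   # closed vs open backbone-without-loops RMSD
_SPLAY_CLOSED = 0.75


def synthetic_kcsa(state: str) -> StructureModel:
    """Synthetic stand-in for a deposited channel-state structure.

    SYNTHETIC: this is *not* the crystal structure; it is an idealised
    backbone tetramer whose activation-gate constriction diameter is
    self-calibrated (bisection on the TM2 gate radius, against the
    direct-enumeration oracle with the default element radii) to the
    published backbone-derived value for the requested state (closed
    5.9 A, intermediate 8.3 A, open 11.8 A), and whose C-terminal TM2
    splay is calibrated so the closed/open backbone-without-loops RMSD
    is 4 A. It exercises the full preparation/selection/measurement
    chain when the deposited structures are unavailable.
    """
    if state not in _STATE_PRESETS:
        raise ValueError(f"unknown state {state!r}; "
                         f"choose from {sorted(_STATE_PRESETS)}")
    target = _STATE_PRESETS[state]
    splay = _calibrated_splay(state)

    def measured(gate_r: float) -> float:
        m = _assemble_tetramer(gate_r, splay)
        return enumerated_gate_diameter(m, _DEFAULT_RADII)

    lo, hi = 0.45, 1.35
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        if measured(mid) < target:
            lo = mid
        else:
            hi = mid
    gate_r = 0.5 * (lo + hi)
    model = _assemble_tetramer(gate_r, splay)
    if state == "closed":
        # wild-type already: arginine at 117
        model = _relabel(model, 117, "ARG")
    else:
        # deposited intermediate/open carry Q117; wild-type correction
        # (relabel to ARG) is left to the preparation step
        model = _relabel(model, 117, "GLN")
    return model


def _relabel(model: StructureModel, resseq: int, name: str) -> StructureModel:
    names = model.residue_name.copy()
    names[model.residue_seq == resseq] = name
    model.residue_name = names
    return model


def _calibrated_splay(state: str) -> float:
    """C-terminal splay radius per state; the open value solves
    RMSD(closed, open) = 4 A over backbone without loops."""
    if state == "closed":
        return _SPLAY_CLOSED
    open_splay = _solve_open_splay()
    if state == "open":
        return open_splay
    return 0.5 * (_SPLAY_CLOSED + open_splay)  # intermediate: midpoint


_SPLAY_CACHE: dict[str, float] = {}


def _solve_open_splay() -> float:
    if "open" in _SPLAY_CACHE:
        return _SPLAY_CACHE["open"]
    from .collective import rmsd as _rmsd
    from .structio import resolve_selection

    spec = SelectionSpec()
    closed = _assemble_tetramer(0.70, _SPLAY_CLOSED)
    idx = resolve_selection(closed, spec)

    def f(splay: float) -> float:
        open_ = _assemble_tetramer(1.00, splay)
        return _rmsd(closed.coords, open_.coords, idx)

    lo, hi = _SPLAY_CLOSED + 0.05, 3.5
    if f(hi) < _RMSD_TARGET_NM:
        _SPLAY_CACHE["open"] = hi
        return hi
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        if f(mid) < _RMSD_TARGET_NM:
            lo = mid
        else:
            hi = mid
    _SPLAY_CACHE["open"] = 0.5 * (lo + hi)
    return _SPLAY_CACHE["open"]
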