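"""Per-frame structural metrics for gating trajectories.

chi1 rotamer angles with up/down classification (the phenylalanine
gating switches live in two chi1 basins: up around -63.5 deg, down
around -175.5 deg, the latter wrapping across -180), state-fraction
time series, opposite-subunit Calpha distances (the classic
activation-gate opening measure at the bundle crossing), geometric
hydrogen-bond counting, and RMSD time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import NM_TO_ANG
from .collective import Trajectory, rmsd
from .structio import SelectionError, StructureModel

__all__ = [
    "RotamerTrace",
    "wrap_angle",
    "dihedral",
    "chi1",
    "classify_rotamer",
    "state_fractions",
    "opposite_distance",
    "hbond_count",
    "rmsd_timeseries",
    "UP_RANGE",
    "DOWN_RANGE",
]

#: printed chi1 ranges (degrees) of the up and down rotamer states
UP_RANGE = (-72.0, -55.0)
DOWN_RANGE = (-185.0, -166.0)  # crosses the branch cut: [-180,-166] u [175,180]

#: gamma atom per residue type for chi1 (N-CA-CB-<gamma>)
_GAMMA_ATOM = {
    "VAL": "CG1", "ILE": "CG1", "THR": "OG1", "SER": "OG",
    "CYS": "SG", "ALA": None,
}


def wrap_angle(a):
    """Wrap degrees to (-180, 180]."""
    return -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Standard convention (matches biotite and MDAnalysis): looking down
    the p1->p2 bond, the far bond rotated clockwise from the near bond
    is positive.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b1 = b1 / np.linalg.norm(b1)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


@dataclass
class RotamerTrace:
    """chi1 time series of one residue plus its per-frame state."""

    chain: str
    resseq: int
    resname: str
    times: np.ndarray   # ps
    chi1: np.ndarray    # degrees in (-180, 180]
    states: np.ndarray  # 'up' | 'down' | 'unassigned'


def chi1(
    coords: np.ndarray, model: StructureModel, chain: str, resseq: int
) -> float:
    """chi1 = N-CA-CB-gamma dihedral (degrees) of one residue.

    Returns NaN (with a warning) when a required atom is absent, e.g.
    for glycine/alanine or backbone-only models.
    """
    import warnings

    sel = (model.chain_id == chain) & (model.residue_seq == resseq)
    if not np.any(sel):
        raise SelectionError(f"residue {chain}/{resseq} not in model")
    resname = str(model.residue_name[sel][0])
    gamma = _GAMMA_ATOM.get(resname, "CG")
    names_needed = ["N", "CA", "CB", gamma]
    if gamma is None:
        warnings.warn(f"{resname} {chain}/{resseq} has no chi1", stacklevel=2)
        return float("nan")
    pts = []
    for name in names_needed:
        idx = np.flatnonzero(sel & (model.atom_name == name))
        if len(idx) == 0:
            warnings.warn(
                f"missing atom {name} for chi1 of {chain}/{resseq}",
                stacklevel=2,
            )
            return float("nan")
        pts.append(coords[idx[0]])
    return dihedral(*pts)


def _in_circular_range(angle: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership of wrapped angles in the closed interval [lo, hi],
    where lo/hi may extend past +-180 (circular interpretation)."""
    a = wrap_angle(angle)
    width = hi - lo
    rel = np.mod(a - lo, 360.0)
    return rel <= width + 1e-12


def classify_rotamer(
    angle,
    up_range: tuple[float, float] = UP_RANGE,
    down_range: tuple[float, float] = DOWN_RANGE,
    mode: str = "strict",
):
    """Classify chi1 angles into 'up' / 'down' (/ 'unassigned').

    strict: inside the printed up range -> up; inside the printed down
    range (circularly, so +176 deg counts as down) -> down; anything
    else -> unassigned. nearest: assign by the smaller circular
    distance to the two range centers, never unassigned.
    """
    a = np.atleast_1d(np.asarray(angle, dtype=float))
    out = np.full(a.shape, "unassigned", dtype="U10")
    if mode == "strict":
        out[_in_circular_range(a, *up_range)] = "up"
        out[_in_circular_range(a, *down_range)] = "down"
    elif mode == "nearest":
        up_c = 0.5 * (up_range[0] + up_range[1])
        down_c = 0.5 * (down_range[0] + down_range[1])
        d_up = np.abs(wrap_angle(a - up_c))
        d_down = np.abs(wrap_angle(a - down_c))
        out[:] = np.where(d_up <= d_down, "up", "down")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.ndim(angle) == 0:
        return str(out[0])
    return out


def state_fractions(traces: list[RotamerTrace]) -> pd.DataFrame:
    """Per-frame percentage of residues in the up and down states.

    Unassigned frames are excluded from the denominator (their share
    is reported separately), mirroring a strict two-state readout.
    """
    if not traces:
        raise ValueError("no rotamer traces given")
    times = traces[0].times
    for t in traces[1:]:
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise ValueError("traces do not share a time grid")
    states = np.stack([t.states for t in traces])  # (n_res, n_frames)
    n_up = np.sum(states == "up", axis=0)
    n_down = np.sum(states == "down", axis=0)
    n_un = np.sum(states == "unassigned", axis=0)
    denom = np.maximum(n_up + n_down, 1)
    return pd.DataFrame(
        {
            "time_ps": times,
            "pct_up": 100.0 * n_up / denom,
            "pct_down": 100.0 * n_down / denom,
            "pct_unassigned": 100.0 * n_un / len(traces),
        }
    )


def opposite_distance(
    coords: np.ndarray,
    model: StructureModel,
    resseq: int,
    atom_name: str = "CA",
    chain_pairing: list[tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Diagonal subunit-pair distances (Angstrom) at one residue.

    For the four-chain channel the two diagonals are (A, C) and
    (B, D); the mean of both is the default opening measure, with the
    individual pairs also reported.
    """
    chains = model.chains()
    if chain_pairing is None:
        if len(chains) % 2:
            raise ValueError("need an even chain count for diagonal pairs")
        half = len(chains) // 2
        chain_pairing = [(chains[i], chains[i + half]) for i in range(half)]
    out: dict[str, float] = {}
    vals = []
    for c1, c2 in chain_pairing:
        i = model.find_atom(c1, resseq, atom_name)
        j = model.find_atom(c2, resseq, atom_name)
        d = float(np.linalg.norm(coords[i] - coords[j])) * NM_TO_ANG
        out[f"{c1}-{c2}"] = d
        vals.append(d)
    out["mean"] = float(np.mean(vals))
    return out


def hbond_count(
    coords: np.ndarray,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
) -> int:
    """Geometric hydrogen-bond count.

    ``donors`` are (donor-heavy-atom, attached-hydrogen) index pairs,
    ``acceptors`` heavy-atom indices. A bond is counted when the D-A
    distance is <= ``d_cut`` (nm) and the H-D-A angle (at the donor,
    between the D->H and D->A directions) is <= ``angle_cut`` degrees.
    """
    import warnings

    if not donors or not acceptors:
        warnings.warn("empty donor or acceptor set; H-bond count is 0",
                      stacklevel=2)
        return 0
    count = 0
    acc = np.asarray(acceptors, dtype=int)
    for d_idx, h_idx in donors:
        dvec = coords[acc] - coords[d_idx]
        dist = np.linalg.norm(dvec, axis=1)
        hvec = coords[h_idx] - coords[d_idx]
        hnorm = np.linalg.norm(hvec)
        cosang = (dvec @ hvec) / np.maximum(dist * hnorm, 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (dist <= d_cut) & (ang <= angle_cut) & (acc != d_idx)
        count += int(np.sum(ok))
    return count


def rmsd_timeseries(
    traj: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) against a fixed reference frame."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != traj.n_atoms:
        raise SelectionError("reference does not match trajectory atoms")
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        out[i] = rmsd(frame, reference, selection, fit=fit) * NM_TO_ANG
    return out


def replica_mean_sd(series_list: list[np.ndarray]):
    """Replica-averaged mean and SD of equal-length time series."""
    arr = np.stack(series_list)
    return arr.mean(axis=0), arr.std(axis=0, ddof=0)
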