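"""Superposition, RMSD, covariance PCA and the difference eigenvector.

The reaction coordinate for activation gating is a single collective
vector: the first (and only non-trivial) eigenvector of a covariance PCA
over a two-frame "trajectory" holding the closed and open conformations.
For two frames this eigenvector is the normalised fitted coordinate
difference, so projecting a structure onto it measures progress along the
closed -> open pathway in nm. All superpositions are least-squares Kabsch
fits restricted to a fit selection (by default the same backbone-without-
loops atoms as the PCA), which removes rigid-body motion from every
projection and RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import (
    SelectionError,
    SelectionSpec,
    StructureModel,
    resolve_selection,
)

__all__ = [
    "CollectiveVector",
    "Trajectory",
    "kabsch_fit",
    "rmsd",
    "covariance_pca",
    "build_difference_ev",
    "project",
    "fit_trajectory",
    "DegenerateFitError",
]

#: eigenvalues below this (nm^2) count as numerically zero rank
EIGEN_RANK_TOL = 1e-10


class DegenerateFitError(ValueError):
    """Fit atom set is too small or collinear for a unique rotation."""


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_frames, n_atoms, 3) in nm."""

    frames: np.ndarray
    times: np.ndarray  # ps
    model: StructureModel | None = None  # shared atom metadata

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class CollectiveVector:
    """A unit 3N-direction over a selected atom set plus its reference.

    ``direction`` is flat (3 * len(atom_indices),) with unit Euclidean
    norm; ``reference_coords`` are the fitted reference coordinates of
    the selected atoms (nm); ``fit_indices`` (model indices, a subset of
    or equal to ``atom_indices``) define the superposition used before
    every projection.
    """

    atom_indices: np.ndarray
    reference_coords: np.ndarray
    direction: np.ndarray
    fit_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    mass_weighted: bool = False

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.reference_coords = np.asarray(self.reference_coords, float)
        self.direction = np.asarray(self.direction, dtype=float).ravel()
        if self.fit_indices is None:
            self.fit_indices = self.atom_indices.copy()
        self.fit_indices = np.asarray(self.fit_indices, dtype=int)
        if len(self.direction) != 3 * len(self.atom_indices):
            raise ValueError("direction length must be 3 * n selected atoms")
        nrm = float(np.linalg.norm(self.direction))
        if abs(nrm - 1.0) > 1e-10:
            raise ValueError(f"direction not normalised (|v| = {nrm})")
        if not np.all(np.isin(self.fit_indices, self.atom_indices)):
            raise ValueError("fit_indices must be a subset of atom_indices")

    # positions of fit atoms inside the selected-atom arrays
    def _fit_positions(self) -> np.ndarray:
        lookup = {int(a): i for i, a in enumerate(self.atom_indices)}
        return np.array([lookup[int(a)] for a in self.fit_indices])

    def save(self, path) -> None:
        """Serialise to a plain-text columnar file (documented header)."""
        fitset = set(int(i) for i in self.fit_indices)
        with open(path, "w") as fh:
            fh.write("# gatekit CollectiveVector v1\n")
            fh.write(f"# mass_weighted {int(self.mass_weighted)}\n")
            fh.write("# columns: atom_index in_fit ref_x ref_y ref_z "
                      "dx dy dz (nm)\n")
            d = self.direction.reshape(-1, 3)
            for k, idx in enumerate(self.atom_indices):
                r = self.reference_coords[k]
                fh.write(
                    f"{int(idx)} {int(int(idx) in fitset)} "
                    f"{r[0]:.9f} {r[1]:.9f} {r[2]:.9f} "
                    f"{d[k, 0]:.12e} {d[k, 1]:.12e} {d[k, 2]:.12e}\n"
                )

    @classmethod
    def load(cls, path) -> "CollectiveVector":
        mass_weighted = False
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "mass_weighted" in line:
                        mass_weighted = bool(int(line.split()[-1]))
                    continue
                rows.append(line.split())
        if not rows:
            raise ValueError(f"empty collective-vector file: {path}")
        arr = np.array(rows, dtype=float)
        direction = arr[:, 5:8].ravel()
        direction /= np.linalg.norm(direction)
        return cls(
            atom_indices=arr[:, 0].astype(int),
            reference_coords=arr[:, 2:5],
            direction=direction,
            fit_indices=arr[arr[:, 1] > 0.5, 0].astype(int),
            mass_weighted=mass_weighted,
        )


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
):
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The rotation/translation minimising the squared deviation over
    ``fit_indices`` (all atoms if None) is computed and applied to every
    mobile atom. Returns ``(rotation (3,3), translation (3,), fitted)``
    such that ``fitted = mobile @ R.T + t`` with det(R) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    fit_indices = np.asarray(fit_indices, dtype=int)
    if len(fit_indices) < 3:
        raise DegenerateFitError("need >= 3 fit atoms for a unique rotation")
    mob = mobile[fit_indices]
    ref = reference[fit_indices]
    cm_mob = mob.mean(axis=0)
    cm_ref = ref.mean(axis=0)
    mc = mob - cm_mob
    # collinearity check: centered fit coords must span a plane
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30) or sv[0] < 1e-14:
        raise DegenerateFitError(
            "fit atoms are (near-)collinear; rotation is not unique"
        )
    rot, _ = Rotation.align_vectors(ref - cm_ref, mc)
    R = rot.as_matrix()
    t = cm_ref - cm_mob @ R.T
    fitted = mobile @ R.T + t
    return R, t, fitted


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    indices: np.ndarray | None = None,
    fit: bool = True,
    fit_indices: np.ndarray | None = None,
) -> float:
    """Root-mean-square deviation (nm) over ``indices``, after an
    optional Kabsch fit of ``a`` onto ``b`` (fit over ``fit_indices``,
    defaulting to ``indices``). Symmetric in its arguments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if indices is None:
        indices = np.arange(len(a))
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        raise SelectionError("empty index set for RMSD")
    if fit:
        _, _, a = kabsch_fit(
            a, b, fit_indices if fit_indices is not None else indices
        )
    d = a[indices] - b[indices]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def fit_trajectory(
    traj: Trajectory, indices: np.ndarray, reference_frame: int = 0
) -> Trajectory:
    """Superpose every frame onto frame ``reference_frame`` over ``indices``."""
    ref = traj.frames[reference_frame]
    fitted = np.empty_like(traj.frames)
    for i, frame in enumerate(traj.frames):
        _, _, fitted[i] = kabsch_fit(frame, ref, indices)
    return Trajectory(frames=fitted, times=traj.times.copy(), model=traj.model)


def covariance_pca(
    traj: Trajectory,
    indices: np.ndarray | None = None,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
):
    """PCA of positional fluctuations over the selected atoms.

    Frames are assumed pre-fitted (see :func:`fit_trajectory`). The
    covariance matrix of the flattened selected coordinates is
    diagonalised; eigenvalues (nm^2) are returned in descending order
    with orthonormal eigenvectors as columns. At most ``n_frames - 1``
    eigenvalues exceed the rank tolerance.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance PCA needs >= 2 frames (rank 0 otherwise)")
    if indices is None:
        indices = np.arange(traj.n_atoms)
    indices = np.asarray(indices, dtype=int)
    x = traj.frames[:, indices, :].reshape(traj.n_frames, -1)
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted PCA requires masses")
        w = np.sqrt(np.repeat(np.asarray(masses, float)[indices], 3))
        x = x * w[None, :]
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evals, evecs[:, order]


def build_difference_ev(
    closed: StructureModel,
    open_: StructureModel,
    spec: SelectionSpec,
    mass_weighted: bool = False,
) -> CollectiveVector:
    """Reaction coordinate between two conformations.

    Builds the two-frame trajectory (closed, open), fits the open frame
    onto the closed one over the selection, and takes the single
    non-zero PCA eigenvector as the collective direction. The sign is
    oriented so that the open conformation projects positive
    ("opening" increases the coordinate); the closed conformation
    projects to exactly 0 and the open one to the path length |dx|.
    """
    idx_c = resolve_selection(closed, spec)
    idx_o = resolve_selection(open_, spec)
    keys_c = [closed.atom_keys()[i] for i in idx_c]
    keys_o = [open_.atom_keys()[i] for i in idx_o]
    if keys_c != keys_o:
        only_c = sorted(set(keys_c) - set(keys_o))[:5]
        only_o = sorted(set(keys_o) - set(keys_c))[:5]
        raise SelectionError(
            "selection resolves to different atoms in the two models; "
            f"only-closed {only_c}, only-open {only_o}"
        )
    xc = closed.coords[idx_c]
    # fit the open selection onto the closed selection
    _, _, fitted_sel = kabsch_fit(open_.coords[idx_o], xc)
    traj = Trajectory(
        frames=np.stack([xc, fitted_sel]),
        times=np.array([0.0, 1.0]),
    )
    evals, evecs = covariance_pca(traj)
    direction = evecs[:, 0]
    diff = (fitted_sel - xc).ravel()
    if float(direction @ diff) < 0:
        direction = -direction
    return CollectiveVector(
        atom_indices=idx_c,
        reference_coords=xc,
        direction=direction / np.linalg.norm(direction),
        fit_indices=idx_c,
        mass_weighted=mass_weighted,
    )


def project(coords: np.ndarray, cv: CollectiveVector) -> float:
    """Projection s (nm) of full-model coordinates onto the collective
    vector: fit the selected atoms onto the reference (over the fit
    subset), then s = direction . (fitted - reference)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] <= int(cv.atom_indices.max()):
        raise SelectionError(
            "coordinates do not cover the collective vector's atoms"
        )
    sel = coords[cv.atom_indices]
    fit_pos = cv._fit_positions()
    _, _, fitted = kabsch_fit(sel, cv.reference_coords, fit_pos)
    return float(cv.direction @ (fitted - cv.reference_coords).ravel())
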