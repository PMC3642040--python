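"""Structure I/O, channel preparation and atom selections.

A :class:`StructureModel` is the unit of structural data: a flat, ordered
table of atoms (serial, name, residue, chain, element) with coordinates in
nm. PDB files store Angstrom; conversion happens only at the I/O boundary.

Selections are expressed as a :class:`SelectionSpec`: named inclusive
residue-number segments (transmembrane helices, pore helix, selectivity
filter, loops), a backbone atom-name set, and an optional chain subset.
The shipped KcsA preset marks the segments used for the
"backbone without loops" selection that underlies every RMSD, PCA and
reaction-coordinate computation in the gating analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import ANG_TO_NM, NM_TO_ANG

__all__ = [
    "StructureModel",
    "SelectionSpec",
    "KCSA_SEGMENTS",
    "BACKBONE_ATOMS",
    "read_pdb",
    "write_pdb",
    "prepare_channel",
    "resolve_selection",
    "relabel_residue",
    "StructureError",
    "SelectionError",
]

#: Default backbone atom-name set. The analysis convention treats the four
#: heavy main-chain atoms as "backbone"; configurable per selection.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Segment preset for the KcsA pore domain (residues 29-118). Loop segments
#: are the ones excluded by "backbone without loops" selections; ranges are
#: inclusive and overridable from config.
KCSA_SEGMENTS: dict[str, tuple[int, int]] = {
    "TM1": (29, 51),
    "loop_turret": (52, 61),
    "P-helix": (62, 74),
    "SF": (75, 79),
    "loop_sf_tm2": (80, 85),
    "TM2": (86, 118),
}


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


class SelectionError(ValueError):
    """A selection resolved to nothing or referenced absent atoms."""


@dataclass
class StructureModel:
    """Ordered atom records with coordinates in nm.

    Invariants: positions finite; (chain_id, residue_seq, atom_name)
    unique; record order is stable under read -> write round-trips.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_seq: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    coords: np.ndarray  # (n_atoms, 3) nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in structure")
        keys = list(zip(self.chain_id, self.residue_seq, self.atom_name))
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise StructureError(
                        f"duplicate atom record (chain {k[0]!r}, residue "
                        f"{k[1]}, atom {k[2]!r})"
                    )
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        out: list[str] = []
        for c in self.chain_id:
            if c not in out:
                out.append(str(c))
        return out

    def subset(self, indices: np.ndarray) -> "StructureModel":
        indices = np.asarray(indices, dtype=int)
        return StructureModel(
            serial=self.serial[indices],
            atom_name=self.atom_name[indices],
            residue_name=self.residue_name[indices],
            residue_seq=self.residue_seq[indices],
            chain_id=self.chain_id[indices],
            element=self.element[indices],
            coords=self.coords[indices].copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        out = StructureModel(
            serial=self.serial.copy(),
            atom_name=self.atom_name.copy(),
            residue_name=self.residue_name.copy(),
            residue_seq=self.residue_seq.copy(),
            chain_id=self.chain_id.copy(),
            element=self.element.copy(),
            coords=np.array(coords, dtype=float),
        )
        if out.coords.shape != self.coords.shape:
            raise StructureError("replacement coords have wrong shape")
        return out

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return list(
            zip(
                (str(c) for c in self.chain_id),
                (int(r) for r in self.residue_seq),
                (str(a) for a in self.atom_name),
            )
        )

    def find_atom(self, chain: str, resseq: int, name: str) -> int:
        mask = (
            (self.chain_id == chain)
            & (self.residue_seq == resseq)
            & (self.atom_name == name)
        )
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise SelectionError(
                f"atom (chain {chain!r}, residue {resseq}, name {name!r}) "
                "not found"
            )
        return int(idx[0])


@dataclass
class SelectionSpec:
    """Named residue segments plus a backbone atom-name filter.

    Segments whose name starts with ``loop`` are treated as loops and are
    dropped unless ``include_loops`` is set. ``chains=None`` means all
    chains.
    """

    segment_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(KCSA_SEGMENTS)
    )
    backbone_atom_names: frozenset = BACKBONE_ATOMS
    include_loops: bool = False
    chains: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ranges = sorted(self.segment_ranges.values())
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if a1 >= b0:
                raise SelectionError(
                    f"segment ranges overlap: ({a0},{a1}) and ({b0},{b1})"
                )
        for name, (lo, hi) in self.segment_ranges.items():
            if lo > hi:
                raise SelectionError(f"segment {name!r} has start > end")

    def is_loop(self, segment: str) -> bool:
        return segment.lower().startswith("loop")

    def active_segments(self) -> dict[str, tuple[int, int]]:
        return {
            n: r
            for n, r in self.segment_ranges.items()
            if self.include_loops or not self.is_loop(n)
        }

    def restricted_to_chains(self, chains) -> "SelectionSpec":
        return replace(self, chains=tuple(chains))


def _from_atom_array(arr: struc.AtomArray) -> StructureModel:
    serial = getattr(arr, "serial", None)
    if serial is None or np.all(serial == 0):
        serial = np.arange(1, arr.array_length() + 1)
    element = np.array(
        [e if e else n[:1] for e, n in zip(arr.element, arr.atom_name)]
    )
    return StructureModel(
        serial=np.asarray(serial, dtype=int),
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        residue_name=np.asarray(arr.res_name, dtype="U5"),
        residue_seq=np.asarray(arr.res_id, dtype=int),
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        element=np.asarray(element, dtype="U2"),
        coords=np.asarray(arr.coord, dtype=float) * ANG_TO_NM,
    )


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = model.coords * NM_TO_ANG
    arr.chain_id = model.chain_id.astype("U4")
    arr.res_id = model.residue_seq.astype(int)
    arr.res_name = model.residue_name.astype("U5")
    arr.atom_name = model.atom_name.astype("U6")
    arr.element = model.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def read_pdb(path) -> StructureModel:
    """Read ATOM/HETATM records into a :class:`StructureModel` (nm).

    Only the first model is used; alternate locations collapse to the
    primary one (altloc ' ' or 'A'). Raises :class:`StructureError` on
    an empty file, a file without coordinate records, or duplicate
    (chain, residue, atom) keys.
    """
    try:
        pdb = PDBFile.read(str(path))
    except FileNotFoundError:
        raise
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises on empty coordinate blocks
        raise StructureError(f"no ATOM records readable from {path}: {exc}")
    if arr.array_length() == 0:
        raise StructureError(f"no ATOM records in {path}")
    return _from_atom_array(arr)


def write_pdb(model: StructureModel, path) -> None:
    """Write fixed-column PDB ATOM records (coordinates in Angstrom)."""
    if np.any(np.abs(model.coords) * NM_TO_ANG >= 10000):
        raise StructureError(
            "coordinates exceed 9999 Angstrom; PDB fixed columns overflow"
        )
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model))
    pdb.write(str(path))


def prepare_channel(
    model: StructureModel,
    first_res: int = 29,
    last_res: int = 118,
) -> StructureModel:
    """Trim every chain to the inclusive residue range [first_res, last_res].

    This is the length-equalisation step applied to the closed,
    intermediate and open channel structures before any comparison: the
    inclusive default range 29-118 keeps 90 residues per chain. Chains
    that do not cover the full range are kept but trigger a coverage
    warning.
    """
    if first_res > last_res:
        raise ValueError(
            f"first_res ({first_res}) must not exceed last_res ({last_res})"
        )
    keep = (model.residue_seq >= first_res) & (model.residue_seq <= last_res)
    if not np.any(keep):
        raise StructureError(
            f"no residues in range {first_res}-{last_res}; nothing to keep"
        )
    out = model.subset(np.flatnonzero(keep))
    expected = last_res - first_res + 1
    for chain in out.chains():
        present = sorted(set(out.residue_seq[out.chain_id == chain]))
        if len(present) < expected:
            missing = sorted(
                set(range(first_res, last_res + 1)) - set(present)
            )
            warnings.warn(
                f"chain {chain}: only {len(present)}/{expected} residues in "
                f"{first_res}-{last_res}; missing {missing[:10]}"
                + ("..." if len(missing) > 10 else ""),
                stacklevel=2,
            )
    return out


def residue_counts(model: StructureModel) -> dict[str, int]:
    """Residues per chain, for coverage reports."""
    return {
        c: len(set(model.residue_seq[model.chain_id == c]))
        for c in model.chains()
    }


def resolve_selection(
    model: StructureModel, spec: SelectionSpec
) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to sorted atom indices.

    Deterministic: the result is the sorted index list of atoms whose
    name is in the backbone set and whose residue number falls in an
    active (non-loop unless requested) segment, restricted to the
    requested chains. Invariant to permutations of atom records within
    a residue up to index renumbering.
    """
    mask = np.zeros(model.n_atoms, dtype=bool)
    missing: list[str] = []
    for name, (lo, hi) in spec.active_segments().items():
        seg = (model.residue_seq >= lo) & (model.residue_seq <= hi)
        if not np.any(seg):
            missing.append(name)
        mask |= seg
    if missing:
        warnings.warn(
            f"segments with no residues present in model: {missing}",
            stacklevel=2,
        )
    mask &= np.isin(model.atom_name, sorted(spec.backbone_atom_names))
    if spec.chains is not None:
        mask &= np.isin(model.chain_id, list(spec.chains))
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError("selection resolved to zero atoms")
    return np.sort(idx)


def relabel_residue(
    model: StructureModel,
    resseq: int,
    new_name: str,
    chains=None,
) -> StructureModel:
    """Rename a residue in place (e.g. the Q117R wild-type correction).

    Name-only: no side-chain rebuilding, since every computation on
    crystal inputs here is backbone-based.
    """
    mask = model.residue_seq == resseq
    if chains is not None:
        mask &= np.isin(model.chain_id, list(chains))
    if not np.any(mask):
        raise SelectionError(f"residue {resseq} not found for relabeling")
    names = model.residue_name.copy().astype("U5")
    names[mask] = new_name
    out = model.subset(np.arange(model.n_atoms))
    out.residue_name = names
    return out
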