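"""Structure/trajectory data model, selections, superposition and centers of mass.

Coordinates are in Å, times in ps, angles in degrees.  Atom indexing is
0-based internally; residue numbers are the 1-based author numbers of the
input structure and are never renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MDGateError",
    "SelectionError",
    "AtomRecord",
    "Structure",
    "Frame",
    "Trajectory",
    "DomainDefinition",
    "SelectionSpec",
    "SuperpositionResult",
    "DEFAULT_DOMAINS",
    "ATOMIC_MASSES",
    "select",
    "superpose",
    "center_of_mass",
    "masses_for",
]


class MDGateError(Exception):
    """Base class for all errors raised by this package."""


class SelectionError(MDGateError):
    """An atom selection could not be resolved against a structure."""


# Standard atomic masses (u) for the elements that occur in protein/membrane
# systems with monatomic ions; unknown elements fall back to carbon with a
# warning at lookup time.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CL": 35.45, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "F": 18.998, "BR": 79.904, "I": 126.904, "FE": 55.845,
    "ZN": 65.38,
}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: PDB-convention name, author residue numbering."""

    atom_index: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # (3,) Å

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_index}: position must be a finite 3-vector")
        if self.residue_number < 1:
            raise ValueError(f"atom {self.atom_index}: residue_number must be >= 1")
        if not self.chain_id:
            raise ValueError(f"atom {self.atom_index}: chain_id must be nonempty")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered set of atoms with optional periodic box.

    Fields are parallel arrays over atoms (column layout, like an
    MDAnalysis AtomGroup); ``atom(i)`` materializes a single
    :class:`AtomRecord`.  ``box`` is ``(lx, ly, lz, alpha, beta, gamma)``
    in Å / degrees, or ``None``.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    positions: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype="U4")
        self.chains = np.asarray(self.chains, dtype="U2")
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.names)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions shape {self.positions.shape} != ({n}, 3)")
        for arr, what in ((self.elements, "elements"), (self.resids, "resids"),
                          (self.resnames, "resnames"), (self.chains, "chains")):
            if len(arr) != n:
                raise ValueError(f"{what} length {len(arr)} != n_atoms {n}")
        if n == 0:
            raise ValueError("empty structure")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in structure")
        if np.any(self.resids < 1):
            raise ValueError("residue numbers must be >= 1")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (6,) or np.any(self.box[:3] <= 0):
                raise ValueError("box must be 3 positive lengths + 3 angles")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(i, str(self.names[i]), str(self.elements[i]),
                          int(self.resids[i]), str(self.resnames[i]),
                          str(self.chains[i]), self.positions[i])

    def with_positions(self, positions: np.ndarray) -> "Structure":
        return replace(self, positions=np.asarray(positions, dtype=float))


@dataclass
class Frame:
    positions: np.ndarray          # (N, 3) Å
    box: Optional[np.ndarray]      # (6,) or None
    time: float                    # ps


@dataclass
class Trajectory:
    """Ordered frames of atom positions sharing one topology."""

    topology: Structure
    coordinates: np.ndarray                 # (F, N, 3) Å
    boxes: Optional[np.ndarray] = None      # (F, 6) or None
    times: Optional[np.ndarray] = None      # (F,) ps

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {self.coordinates.shape[1] if self.coordinates.ndim == 3 else '?'} atoms "
                f"per frame but topology has {self.topology.n_atoms}")
        f = self.coordinates.shape[0]
        if self.times is None:
            self.times = np.arange(f, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != f:
            raise ValueError("times length != n_frames")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be non-decreasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (f, 6):
                raise ValueError("boxes must be (n_frames, 6)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        box = self.boxes[i] if self.boxes is not None else (
            self.topology.box if self.topology.box is not None else None)
        return Frame(self.coordinates[i], box, float(self.times[i]))

    def iter_frames(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain: a chain plus sorted, non-overlapping residue intervals."""

    name: str
    chain_id: str
    residue_ranges: tuple  # of (lo, hi) inclusive

    def __post_init__(self):
        ranges = tuple((int(lo), int(hi)) for lo, hi in self.residue_ranges)
        last = None
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"domain {self.name}: empty interval ({lo}, {hi})")
            if last is not None and lo <= last:
                raise ValueError(f"domain {self.name}: intervals must be sorted and non-overlapping")
            last = hi
        object.__setattr__(self, "residue_ranges", ranges)

    def contains(self, resid: int) -> bool:
        return any(lo <= resid <= hi for lo, hi in self.residue_ranges)

    def residue_mask(self, resids: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(resids), dtype=bool)
        for lo, hi in self.residue_ranges:
            mask |= (resids >= lo) & (resids <= hi)
        return mask


# Residue spans of the SLC26A9 subdomains in author numbering.
# The TM domain is the union of core and gate.
CORE_RANGES = ((45, 150), (158, 198), (313, 428))
GATE_RANGES = ((199, 312), (429, 499))
STAS_RANGES = ((5, 26), (500, 567), (653, 741))
TM_RANGES = ((45, 150), (158, 499))  # core ∪ gate, merged

DEFAULT_DOMAINS = {
    "core": CORE_RANGES,
    "gate": GATE_RANGES,
    "STAS": STAS_RANGES,
    "TM": TM_RANGES,
}


def domain(name: str, chain_id: str) -> DomainDefinition:
    """A default-span :class:`DomainDefinition` for ``core``/``gate``/``STAS``/``TM``."""
    try:
        return DomainDefinition(name, chain_id, DEFAULT_DOMAINS[name])
    except KeyError:
        raise KeyError(f"unknown domain {name!r}; known: {sorted(DEFAULT_DOMAINS)}") from None


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection: chain, residues (numbers or a domain), atom names."""

    chain_id: Optional[str] = None
    residue_numbers: Optional[tuple] = None
    domain: Optional[DomainDefinition] = None
    atom_names: Optional[tuple] = None

    def __post_init__(self):
        if self.residue_numbers is not None:
            object.__setattr__(self, "residue_numbers", tuple(int(r) for r in self.residue_numbers))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", tuple(str(a) for a in self.atom_names))
        if self.residue_numbers is not None and self.domain is not None:
            raise ValueError("give residue_numbers or a domain, not both")

    def describe(self) -> str:
        parts = []
        if self.chain_id is not None:
            parts.append(f"chain {self.chain_id}")
        if self.domain is not None:
            parts.append(f"domain {self.domain.name} ({self.domain.chain_id})")
        if self.residue_numbers is not None:
            parts.append(f"residues {list(self.residue_numbers)}")
        if self.atom_names is not None:
            parts.append(f"atoms {list(self.atom_names)}")
        return ", ".join(parts) or "<all atoms>"


def select(structure: Structure, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to sorted 0-based atom indices.

    Deterministic and idempotent; raises :class:`SelectionError` if nothing
    matches, naming the unmatched spec.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    if spec.domain is not None:
        mask &= structure.chains == spec.domain.chain_id
        mask &= spec.domain.residue_mask(structure.resids)
    if spec.chain_id is not None:
        mask &= structure.chains == spec.chain_id
    if spec.residue_numbers is not None:
        mask &= np.isin(structure.resids, spec.residue_numbers)
    if spec.atom_names is not None:
        mask &= np.isin(structure.names, spec.atom_names)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection matched no atoms: {spec.describe()}")
    return idx


def find_atom(structure: Structure, chain_id: str, resid: int, atom_name: str = "CA") -> int:
    """Index of a single named atom; error names the residue when absent."""
    idx = np.flatnonzero((structure.chains == chain_id)
                         & (structure.resids == resid)
                         & (structure.names == atom_name))
    if idx.size == 0:
        raise SelectionError(f"no atom {atom_name} in chain {chain_id} residue {resid}")
    return int(idx[0])


def masses_for(structure: Structure, indices: Optional[np.ndarray] = None,
               unit: bool = False) -> np.ndarray:
    """Atomic masses for a selection; ``unit=True`` gives centroid semantics."""
    if indices is None:
        indices = np.arange(structure.n_atoms)
    if unit:
        return np.ones(len(indices))
    masses = np.empty(len(indices))
    for k, i in enumerate(indices):
        el = str(structure.elements[i]).upper().strip()
        if not el:
            # fall back to the first alphabetic character of the atom name
            name = str(structure.names[i]).strip()
            el = next((c for c in name if c.isalpha()), "C").upper()
        masses[k] = ATOMIC_MASSES.get(el, ATOMIC_MASSES.get(el[:1], 12.011))
    return masses


def center_of_mass(positions: np.ndarray, indices: Optional[np.ndarray] = None,
                   masses: Optional[np.ndarray] = None) -> np.ndarray:
    """Mass-weighted mean position; unit masses reduce it to the centroid."""
    pos = np.asarray(positions, dtype=float)
    if indices is not None:
        pos = pos[np.asarray(indices, dtype=int)]
    if pos.shape[0] == 0:
        raise SelectionError("center of mass of an empty selection")
    if masses is None:
        masses = np.ones(pos.shape[0])
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != pos.shape[0]:
        raise ValueError("masses length != number of selected atoms")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference: x -> R x + t."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)
    rmsd: float               # post-fit, Å

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions, dtype=float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: Optional[np.ndarray] = None) -> SuperpositionResult:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    Both inputs are (n, 3) with n >= 3 non-collinear points.  Returns the
    proper rotation (det = +1), translation and the post-fit weighted RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise MDGateError(f"superposition needs >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mc = (w[:, None] * mob).sum(axis=0)
    rc = (w[:, None] * ref).sum(axis=0)
    m0, r0 = mob - mc, ref - rc
    if np.linalg.matrix_rank(m0, tol=1e-8 * max(1.0, np.abs(m0).max())) < 2:
        raise MDGateError("degenerate geometry: points are collinear or coincident")
    h = (w[:, None] * m0).T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    resid = m0 @ rot.T - r0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum()))
    return SuperpositionResult(rot, trans, rmsd)
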