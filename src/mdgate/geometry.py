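"""Domain-level geometric observables of a transporter dimer trajectory.

Implements the gating-geometry measurements: the core–gate tip distance
(Cα 362 – Cα 201), a per-frame dimer reference frame (z = membrane
normal, x = inter-chain TM center-of-mass axis projected ⊥ z, y = z × x)
and the STAS center-of-mass trace in that frame, backbone φ/ψ dihedrals,
helix kink angles from principal-axis fits of flanking Cα windows, salt
bridges, and per-frame RMSD profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (MDGateError, SelectionError, SelectionSpec, Structure,
                   Trajectory, center_of_mass, find_atom, masses_for, select,
                   superpose)

__all__ = [
    "ReferenceFrame",
    "DistanceSeries",
    "DihedralSeries",
    "KinkSeries",
    "SaltBridgeContact",
    "core_gate_distance",
    "dimer_frame",
    "stas_com_trace",
    "backbone_dihedrals",
    "kink_angle",
    "salt_bridge_distance",
    "detect_salt_bridges",
    "rmsd_profile",
    "BASIC_DONOR_ATOMS",
    "ACIDIC_ACCEPTOR_ATOMS",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
]

# Side-chain atoms forming salt bridges: basic nitrogens vs acidic oxygens.
BASIC_DONOR_ATOMS = ("NZ", "NH1", "NH2", "NE")
ACIDIC_ACCEPTOR_ATOMS = ("OD1", "OD2", "OE1", "OE2")
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # Å, N–O, strict "<"

CORE_TIP_RESIDUE = 362   # ASP at the core-domain tip
GATE_TIP_RESIDUE = 201   # GLU at the gate-domain tip


@dataclass
class ReferenceFrame:
    """Right-handed orthonormal frame (origin + axes) for dimer coordinates."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} is not unit length")
            setattr(self, name, v)
        if (abs(self.x_axis @ self.y_axis) > 1e-8
                or abs(self.x_axis @ self.z_axis) > 1e-8
                or abs(self.y_axis @ self.z_axis) > 1e-8):
            raise ValueError("frame axes are not mutually orthogonal")
        if np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) > 1e-8:
            raise ValueError("frame is not right-handed (x × y != z)")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        local = np.column_stack([rel @ self.x_axis, rel @ self.y_axis, rel @ self.z_axis])
        return local[0] if np.asarray(points).ndim == 1 else local


@dataclass
class DistanceSeries:
    values: np.ndarray       # Å, per frame
    label: str
    times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             "time_ps": self.times, "value": self.values,
                             "label": self.label})


@dataclass
class DihedralSeries:
    """Per-frame φ/ψ (degrees, (−180, 180]) for one residue."""

    chain_id: str
    residue_number: int
    phi: Optional[np.ndarray]
    psi: Optional[np.ndarray]
    times: np.ndarray


@dataclass
class KinkSeries:
    values: np.ndarray       # degrees in [0, 180]
    chain_id: str
    residue_number: int
    half_window: int
    times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 180)):
            raise ValueError("kink angles must lie in [0, 180] degrees")


@dataclass(frozen=True)
class SaltBridgeContact:
    donor_chain: str
    donor_resid: int
    donor_resname: str
    donor_atom: str
    acceptor_chain: str
    acceptor_resid: int
    acceptor_resname: str
    acceptor_atom: str
    distance: float
    cutoff: float


def core_gate_distance(traj: Trajectory, chain: str,
                       res_core: int = CORE_TIP_RESIDUE,
                       res_gate: int = GATE_TIP_RESIDUE) -> DistanceSeries:
    """Per-frame Cα–Cα distance between the core and gate domain tips."""
    ia = find_atom(traj.topology, chain, res_core, "CA")
    ib = find_atom(traj.topology, chain, res_gate, "CA")
    values = np.linalg.norm(traj.coordinates[:, ia] - traj.coordinates[:, ib], axis=1)
    label = f"Ca {res_core}-Ca {res_gate} chain {chain}"
    return DistanceSeries(values=values, label=label, times=traj.times)


def dimer_frame(positions: np.ndarray, tm_a: Sequence[int], tm_b: Sequence[int],
                masses_a: Optional[np.ndarray] = None,
                masses_b: Optional[np.ndarray] = None,
                membrane_normal=(0.0, 0.0, 1.0)) -> ReferenceFrame:
    """Dimer reference frame from the TM-domain centers of mass.

    z is the membrane normal (cytoplasm → extracellular); x is the
    component ⊥ z of the vector from chain B's TM COM to chain A's;
    y = z × x; the origin is the midpoint of the two TM COMs.
    """
    com_a = center_of_mass(positions, tm_a, masses_a)
    com_b = center_of_mass(positions, tm_b, masses_b)
    z = np.asarray(membrane_normal, dtype=float)
    z = z / np.linalg.norm(z)
    v = com_a - com_b
    x = v - (v @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise MDGateError("degenerate dimer orientation: inter-chain axis parallel "
                          "to the membrane normal")
    x = x / nx
    y = np.cross(z, x)
    return ReferenceFrame(origin=0.5 * (com_a + com_b), x_axis=x, y_axis=y, z_axis=z)


def stas_com_trace(traj: Trajectory, stas_a: Sequence[int], stas_b: Sequence[int],
                   tm_a: Sequence[int], tm_b: Sequence[int],
                   unit_masses: bool = False,
                   membrane_normal=(0.0, 0.0, 1.0)) -> pd.DataFrame:
    """Per-frame STAS center-of-mass coordinates in the dimer frame.

    Returns a DataFrame with x/y/z per chain; the y column is the one
    histogrammed to characterize lateral STAS motion.
    """
    top = traj.topology
    m_sa = masses_for(top, np.asarray(stas_a), unit=unit_masses)
    m_sb = masses_for(top, np.asarray(stas_b), unit=unit_masses)
    m_ta = masses_for(top, np.asarray(tm_a), unit=unit_masses)
    m_tb = masses_for(top, np.asarray(tm_b), unit=unit_masses)
    rows = []
    for f in range(traj.n_frames):
        pos = traj.coordinates[f]
        frame = dimer_frame(pos, tm_a, tm_b, m_ta, m_tb, membrane_normal)
        la = frame.to_local(center_of_mass(pos, stas_a, m_sa))
        lb = frame.to_local(center_of_mass(pos, stas_b, m_sb))
        rows.append((f, traj.times[f], *la, *lb))
    return pd.DataFrame(rows, columns=["frame", "time_ps",
                                       "x_A", "y_A", "z_A",
                                       "x_B", "y_B", "z_B"])


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees, (−180, 180]) of four points, vectorized
    over a leading frame axis.  IUPAC sign convention (trans = 180°)."""
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    if (np.any(np.linalg.norm(np.cross(b0, b1), axis=1) < 1e-10)
            or np.any(np.linalg.norm(np.cross(b1, b2), axis=1) < 1e-10)):
        raise MDGateError("dihedral undefined: three consecutive atoms are collinear")
    b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.einsum("ij,ij->i", b0, b1n)[:, None] * b1n
    w = b2 - np.einsum("ij,ij->i", b2, b1n)[:, None] * b1n
    x = np.einsum("ij,ij->i", v, w)
    y = np.einsum("ij,ij->i", np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)  # range (−180, 180]
    return ang


def backbone_dihedrals(traj: Trajectory, targets: Sequence, which: str = "both"
                       ) -> list:
    """φ and/or ψ series for (chain, residue) targets.

    φ = C(i−1)–N–CA–C and ψ = N–CA–C–N(i+1); a terminal residue lacking
    the needed neighbor raises an error naming it.
    """
    if which not in ("phi", "psi", "both"):
        raise ValueError("which must be 'phi', 'psi' or 'both'")
    top = traj.topology
    out = []
    for chain, resid in targets:
        phi = psi = None
        n = find_atom(top, chain, resid, "N")
        ca = find_atom(top, chain, resid, "CA")
        c = find_atom(top, chain, resid, "C")
        if which in ("phi", "both"):
            try:
                c_prev = find_atom(top, chain, resid - 1, "C")
            except SelectionError:
                raise MDGateError(
                    f"phi undefined for chain {chain} residue {resid}: no preceding residue") from None
            phi = dihedral(traj.coordinates[:, c_prev], traj.coordinates[:, n],
                           traj.coordinates[:, ca], traj.coordinates[:, c])
        if which in ("psi", "both"):
            try:
                n_next = find_atom(top, chain, resid + 1, "N")
            except SelectionError:
                raise MDGateError(
                    f"psi undefined for chain {chain} residue {resid}: no following residue") from None
            psi = dihedral(traj.coordinates[:, n], traj.coordinates[:, ca],
                           traj.coordinates[:, c], traj.coordinates[:, n_next])
        out.append(DihedralSeries(chain, resid, phi, psi, traj.times))
    return out


def _helix_axis(points: np.ndarray) -> np.ndarray:
    """Helix axis direction of a Cα window, oriented N → C.

    Uses the second differences d_i = p_{i-1} + p_{i+1} − 2 p_i, which for
    an ideal helix are exactly perpendicular to the axis (the rise is
    linear, so the axial component cancels); the axis is the common
    normal, i.e. the smallest-singular-vector of the stacked d_i.  Unlike
    a principal-component fit of the raw points, this is unbiased on
    short helical arcs whose span is not a whole number of turns.
    """
    d = points[:-2] + points[2:] - 2.0 * points[1:-1]
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    axis = vt[-1]
    if axis @ (points[-1] - points[0]) < 0:
        axis = -axis
    return axis


def kink_angle(traj: Trajectory, chain: str, residue: int,
               half_window: int = 6) -> KinkSeries:
    """Helix kink at a residue: angle between helix axes fitted to the
    Cα windows [i−half_window, i−1] and [i+1, i+half_window]."""
    top = traj.topology
    def window_indices(lo, hi):
        idx = []
        for r in range(lo, hi + 1):
            try:
                idx.append(find_atom(top, chain, r, "CA"))
            except SelectionError:
                pass
        return idx
    before = window_indices(residue - half_window, residue - 1)
    after = window_indices(residue + 1, residue + half_window)
    if len(before) < 4 or len(after) < 4:
        raise MDGateError(
            f"kink at chain {chain} residue {residue}: need >= 4 Ca atoms per side in "
            f"spans [{residue - half_window}, {residue - 1}] and "
            f"[{residue + 1}, {residue + half_window}]; found {len(before)} and {len(after)}")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pos = traj.coordinates[f]
        a1 = _helix_axis(pos[before])
        a2 = _helix_axis(pos[after])
        values[f] = np.degrees(np.arccos(np.clip(a1 @ a2, -1.0, 1.0)))
    return KinkSeries(values=values, chain_id=chain, residue_number=residue,
                      half_window=half_window, times=traj.times)


def _min_image(diff: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is not None:
        lengths = box[:3]
        diff = diff - lengths * np.round(diff / lengths)
    return diff


def salt_bridge_distance(traj: Trajectory, atoms_a: Sequence[int],
                         atoms_b: Sequence[int],
                         label: str = "salt bridge") -> DistanceSeries:
    """Per-frame minimum-image distance between two atoms (or the minimum
    over all donor × acceptor pairs when group selections are given)."""
    ia = np.asarray(atoms_a, dtype=int)
    ib = np.asarray(atoms_b, dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("salt-bridge selections must be nonempty")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        diff = frame.positions[ia][:, None, :] - frame.positions[ib][None, :, :]
        d = np.linalg.norm(_min_image(diff, frame.box), axis=-1)
        values[f] = d.min()
    return DistanceSeries(values=values, label=label, times=traj.times)


def detect_salt_bridges(structure: Structure,
                        positions: Optional[np.ndarray] = None,
                        box: Optional[np.ndarray] = None,
                        cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF) -> list:
    """All basic-N / acidic-O contacts closer than ``cutoff`` (strict "<"),
    deduplicated to the closest pair per residue pair."""
    pos = structure.positions if positions is None else np.asarray(positions, dtype=float)
    if box is None:
        box = structure.box
    donors = np.flatnonzero(np.isin(structure.names, BASIC_DONOR_ATOMS))
    acceptors = np.flatnonzero(np.isin(structure.names, ACIDIC_ACCEPTOR_ATOMS))
    contacts = {}
    if donors.size and acceptors.size:
        diff = pos[donors][:, None, :] - pos[acceptors][None, :, :]
        d = np.linalg.norm(_min_image(diff, box), axis=-1)
        for di, ai in zip(*np.nonzero(d < cutoff)):
            i, j = donors[di], acceptors[ai]
            key = ((str(structure.chains[i]), int(structure.resids[i])),
                   (str(structure.chains[j]), int(structure.resids[j])))
            dist = float(d[di, ai])
            if key not in contacts or dist < contacts[key].distance:
                contacts[key] = SaltBridgeContact(
                    donor_chain=str(structure.chains[i]), donor_resid=int(structure.resids[i]),
                    donor_resname=str(structure.resnames[i]), donor_atom=str(structure.names[i]),
                    acceptor_chain=str(structure.chains[j]), acceptor_resid=int(structure.resids[j]),
                    acceptor_resname=str(structure.resnames[j]), acceptor_atom=str(structure.names[j]),
                    distance=dist, cutoff=cutoff)
    return sorted(contacts.values(),
                  key=lambda c: (c.donor_chain, c.donor_resid, c.acceptor_chain, c.acceptor_resid))


def rmsd_profile(traj: Trajectory, selection: Sequence[int],
                 reference_frame: int = 0) -> np.ndarray:
    """Per-frame best-fit RMSD of a selection to a reference frame, after
    superposing on that same selection."""
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise MDGateError("RMSD profile needs a selection of >= 3 atoms")
    ref = traj.coordinates[reference_frame][sel]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        values[f] = superpose(traj.coordinates[f][sel], ref).rmsd
    return values
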