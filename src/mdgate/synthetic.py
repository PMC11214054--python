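"""Synthetic trajectories with known ground truth.

Every analysis stage in this package has a recovery test driven by one of
these kinematic generators — no MD engine involved, no forces, no
membrane.  Each generator takes a frozen config dataclass with an
explicit seed, uses a single private ``numpy.random.Generator`` stream,
and returns a :class:`~mdgate.core.Trajectory` (or sample arrays) plus a
ground-truth record so tests never re-derive truth from the data they
are validating.

What is emulated, and what is not:

* diffusing monatomic anions in a periodic box with a localized binding
  well of configurable stationary occupancy (two-state Markov chain, not
  Langevin dynamics);
* protein-like backbones built from ideal internal coordinates with
  prescribed kink angles and φ/ψ correlation modes;
* two-chain dimer "blob" toys with controllable domain centers of mass;
* on/off (telegraph) salt-bridge distance series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .core import Structure, Trajectory

__all__ = [
    "IonWellConfig",
    "DihedralModeConfig",
    "HelixConfig",
    "TelegraphConfig",
    "DimerToyConfig",
    "gen_ion_trajectory",
    "gen_dihedral_series",
    "gen_kinked_helix",
    "gen_salt_bridge_series",
    "gen_dimer_toy",
]

# Ideal backbone internal coordinates (Å / degrees) used by the helix builder.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ALPHA_PHI = -57.0
ALPHA_PSI = -47.0


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D given chain A–B–C and internal coordinates."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(chi),
                        bond * np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# --------------------------------------------------------------------------
# ion well

@dataclass(frozen=True)
class IonWellConfig:
    """Diffusing anions in a periodic box with one localized binding well.

    The tracked ion follows a two-state (bound/unbound) Markov chain with
    stationary bound probability ``p_bind``; ``switching_rate`` = 1 makes
    the per-frame states i.i.d. so realized occupancy obeys the binomial
    law that the recovery tests assume.  When bound the ion sits uniformly
    within ``well_radius`` of ``well_center`` (default small enough that a
    1 Å grid resolves the well as a single cell).
    """

    box_lengths: tuple = (40.0, 40.0, 40.0)
    n_ions: int = 5
    step_sigma: float = 1.0            # Å per frame random-walk step
    well_center: tuple = (20.5, 20.5, 20.5)
    well_radius: float = 0.4
    p_bind: float = 0.30
    switching_rate: float = 1.0        # per frame; 1.0 → i.i.d. states
    n_frames: int = 2000
    dt: float = 100.0                  # ps between frames
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.p_bind < 1.0):
            raise ValueError("p_bind must lie strictly in (0, 1)")
        if not (0.0 < self.switching_rate <= 1.0):
            raise ValueError("switching_rate must lie in (0, 1]")
        if self.n_ions < 1 or self.n_frames < 1:
            raise ValueError("n_ions and n_frames must be positive")
        lo = np.asarray(self.well_center) - self.well_radius
        hi = np.asarray(self.well_center) + self.well_radius
        if np.any(lo < 0) or np.any(hi > np.asarray(self.box_lengths)):
            raise ValueError("well must lie inside the box")


def gen_ion_trajectory(config: IonWellConfig):
    """Ion-well trajectory plus ground truth.

    The topology carries two static anchor "CA" atoms (residues 128 and
    391, chain A) whose midpoint is the well center, so the binding-site
    constructor and the 9 Å time-series counter work out of the box, then
    ``n_ions`` chloride-like ions.  Returns ``(Trajectory, truth)`` where
    ``truth['bound_fraction']`` is the realized fraction of bound frames.
    """
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box_lengths, dtype=float)
    center = np.asarray(config.well_center, dtype=float)
    anchor_offset = np.array([2.0, 0.0, 0.0])
    anchors = np.stack([center - anchor_offset, center + anchor_offset])

    n_at = 2 + config.n_ions
    names = ["CA", "CA"] + ["CLA"] * config.n_ions
    elements = ["C", "C"] + ["CL"] * config.n_ions
    resids = [128, 391] + list(range(1, config.n_ions + 1))
    resnames = ["PHE", "LEU"] + ["CLA"] * config.n_ions
    chains = ["A", "A"] + ["I"] * config.n_ions

    ion_pos = rng.uniform(0, 1, size=(config.n_ions, 3)) * box
    # tracked ion: index 0 among ions (atom index 2)
    p_on = config.switching_rate * config.p_bind
    p_off = config.switching_rate * (1.0 - config.p_bind)
    bound = rng.random() < config.p_bind  # start from the stationary law
    coords = np.empty((config.n_frames, n_at, 3))
    bound_frames = np.zeros(config.n_frames, dtype=bool)
    for f in range(config.n_frames):
        ion_pos = np.mod(ion_pos + rng.normal(0, config.step_sigma, ion_pos.shape), box)
        if bound:
            bound = rng.random() >= p_off
        else:
            bound = rng.random() < p_on
        bound_frames[f] = bound
        frame_ions = ion_pos.copy()
        if bound:
            u = rng.normal(size=3)
            r = config.well_radius * rng.random() ** (1 / 3)
            frame_ions[0] = center + r * u / np.linalg.norm(u)
        coords[f, :2] = anchors
        coords[f, 2:] = frame_ions
    box6 = np.concatenate([box, [90.0, 90.0, 90.0]])
    top = Structure(names=names, elements=elements, resids=resids,
                    resnames=resnames, chains=chains, positions=coords[0],
                    box=box6)
    traj = Trajectory(topology=top, coordinates=coords,
                      boxes=np.tile(box6, (config.n_frames, 1)),
                      times=np.arange(config.n_frames) * config.dt)
    truth = {"config": asdict(config),
             "bound_fraction": float(bound_frames.mean()),
             "bound_frames": bound_frames.sum().item(),
             "tracked_ion_atom_index": 2,
             "well_center": list(center)}
    return traj, truth


# --------------------------------------------------------------------------
# dihedral correlation modes

@dataclass(frozen=True)
class DihedralModeConfig:
    """(φ, ψ) samples in one of three correlation modes.

    ``crankshaft`` samples along the anti-correlated line ψ = c − φ
    (slope −1) through the branch vertex; ``uncorrelated`` is an isotropic
    Gaussian blob; ``dual`` mixes the crankshaft branch with the
    positively sloped non-crankshaft branch so that all three standard
    probe cells are populated.  The two branches intersect at the vertex
    (−90°, −15°).
    """

    mode: str = "dual"
    vertex: tuple = (-90.0, -15.0)
    branch_sigma: float = 20.0       # spread along a branch, degrees
    noise_sigma: float = 5.0         # isotropic scatter off the branch
    blob_sigma: float = 10.0         # width of the uncorrelated blob
    mixture_weight: float = 0.5      # crankshaft fraction in dual mode
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("crankshaft", "noncrankshaft", "uncorrelated", "dual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.noise_sigma <= 0 or self.branch_sigma <= 0 or self.blob_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if not (0.0 < self.mixture_weight < 1.0):
            raise ValueError("mixture_weight must lie in (0, 1)")


def _branch_samples(rng, vertex, slope, sigma_t, sigma_n, n):
    t = rng.normal(0.0, sigma_t, n)
    phi = vertex[0] + t + rng.normal(0.0, sigma_n, n)
    psi = vertex[1] + slope * t + rng.normal(0.0, sigma_n, n)
    return phi, psi


def gen_dihedral_series(config: DihedralModeConfig):
    """Sample (φ, ψ) pairs; returns ``(phi, psi, truth)``.

    ``truth`` records the mode and, for dual mode, which branch each
    sample came from.
    """
    rng = np.random.default_rng(config.seed)
    v = config.vertex
    if config.mode == "crankshaft":
        phi, psi = _branch_samples(rng, v, -1.0, config.branch_sigma,
                                   config.noise_sigma, config.n_samples)
        truth = {"mode": "crankshaft"}
    elif config.mode == "noncrankshaft":
        phi, psi = _branch_samples(rng, v, +1.0, config.branch_sigma,
                                   config.noise_sigma, config.n_samples)
        truth = {"mode": "noncrankshaft"}
    elif config.mode == "uncorrelated":
        phi = v[0] + rng.normal(0.0, config.blob_sigma, config.n_samples)
        psi = v[1] + rng.normal(0.0, config.blob_sigma, config.n_samples)
        truth = {"mode": "uncorrelated"}
    else:  # dual: crankshaft + noncrankshaft mixture through the same vertex
        crank = rng.random(config.n_samples) < config.mixture_weight
        phi = np.empty(config.n_samples)
        psi = np.empty(config.n_samples)
        pc, sc = _branch_samples(rng, v, -1.0, config.branch_sigma,
                                 config.noise_sigma, int(crank.sum()))
        pn, sn = _branch_samples(rng, v, +1.0, config.branch_sigma,
                                 config.noise_sigma, int((~crank).sum()))
        phi[crank], psi[crank] = pc, sc
        phi[~crank], psi[~crank] = pn, sn
        truth = {"mode": "dual", "crankshaft_fraction": float(crank.mean())}
    phi = np.mod(phi + 180.0, 360.0) - 180.0
    psi = np.mod(psi + 180.0, 360.0) - 180.0
    truth["config"] = asdict(config)
    return phi, psi, truth


# --------------------------------------------------------------------------
# kinked helix

@dataclass(frozen=True)
class HelixConfig:
    """Ideal α-helical backbone with an optional axis kink.

    The backbone (N, CA, C per residue) is chained from ideal internal
    coordinates at (φ, ψ) = (−57°, −47°), which yields the canonical
    ~1.5 Å rise, ~100° twist and ~2.3 Å Cα radius quoted in the nominal
    fields.  Beyond ``kink_residue`` the chain is rotated by
    ``kink_angle`` about an axis through that residue's Cα perpendicular
    to the local helix axis.
    """

    n_residues: int = 15
    start_resid: int = 438
    chain_id: str = "B"
    phi: float = ALPHA_PHI
    psi: float = ALPHA_PSI
    rise: float = 1.5                  # nominal, Å/residue
    twist: float = 100.0               # nominal, degrees/residue
    radius: float = 2.3                # nominal Cα helix radius, Å
    kink_residue: Optional[int] = None
    kink_angle: float = 0.0
    jitter_sigma: float = 0.0          # Å thermal jitter per frame
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.kink_residue is not None:
            last = self.start_resid + self.n_residues - 1
            if not (self.start_resid < self.kink_residue < last):
                raise ValueError(f"kink_residue {self.kink_residue} must be interior "
                                 f"to [{self.start_resid}, {last}]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


def _ideal_backbone(n_residues: int, phi: float, psi: float) -> np.ndarray:
    """(n_residues, 3 atoms, 3) N/CA/C coordinates chained by NeRF."""
    atoms = np.empty((n_residues, 3, 3))
    atoms[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    atoms[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])                 # CA
    ang = np.radians(ANGLE_N_CA_C)
    atoms[0, 2] = atoms[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = atoms[i - 1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_new = _place_atom(ca_prev, c_prev, n_new, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c_new = _place_atom(c_prev, n_new, ca_new, BOND_CA_C, ANGLE_N_CA_C, phi)
        atoms[i] = [n_new, ca_new, c_new]
    return atoms


def gen_kinked_helix(config: HelixConfig):
    """Kinked-helix trajectory; returns ``(Trajectory, truth)`` with the
    configured kink angle as ground truth."""
    rng = np.random.default_rng(config.seed)
    bb = _ideal_backbone(config.n_residues, config.phi, config.psi)
    resids = config.start_resid + np.arange(config.n_residues)
    if config.kink_residue is not None and config.kink_angle != 0.0:
        k = int(config.kink_residue - config.start_resid)
        ca = bb[:, 1, :]
        helix_axis = _first_pc(ca[: k + 1])
        # deterministic perpendicular rotation axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(helix_axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = np.cross(helix_axis, ref)
        rot = _rotation_about(perp, config.kink_angle)
        pivot = bb[k, 1].copy()
        flat = bb.reshape(-1, 3)
        sel = np.repeat(np.arange(config.n_residues) > k, 3)
        flat[sel] = (flat[sel] - pivot) @ rot.T + pivot
        bb = flat.reshape(config.n_residues, 3, 3)
    n_at = config.n_residues * 3
    names = ["N", "CA", "C"] * config.n_residues
    elements = ["N", "C", "C"] * config.n_residues
    at_resids = np.repeat(resids, 3)
    resnames = np.repeat(["ALA"] * config.n_residues, 3)
    chains = [config.chain_id] * n_at
    base = bb.reshape(-1, 3)
    coords = np.tile(base, (config.n_frames, 1, 1))
    if config.jitter_sigma > 0:
        coords = coords + rng.normal(0, config.jitter_sigma, coords.shape)
    top = Structure(names=names, elements=elements, resids=at_resids,
                    resnames=resnames, chains=chains, positions=coords[0])
    traj = Trajectory(topology=top, coordinates=coords)
    truth = {"config": asdict(config), "kink_angle": config.kink_angle,
             "kink_residue": config.kink_residue,
             "phi": config.phi, "psi": config.psi}
    return traj, truth


def _first_pc(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if axis @ (points[-1] - points[0]) < 0:
        axis = -axis
    return axis


# --------------------------------------------------------------------------
# telegraph salt bridge

@dataclass(frozen=True)
class TelegraphConfig:
    """Two atoms whose separation switches between a bridged (low) and an
    open (high) distance with a configured duty cycle at the low state."""

    low: float = 2.8
    high: float = 8.0
    duty_cycle: float = 0.4
    switching_rate: float = 1.0
    n_frames: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (self.low < self.high):
            raise ValueError("low distance must be below high distance")
        if not (0.0 < self.duty_cycle < 1.0):
            raise ValueError("duty_cycle must lie strictly in (0, 1)")
        if not (0.0 < self.switching_rate <= 1.0):
            raise ValueError("switching_rate must lie in (0, 1]")


def gen_salt_bridge_series(config: TelegraphConfig):
    """Two-atom telegraph trajectory (LYS458 Nζ chain B vs an acidic
    carboxylate O of residue 709 chain A); returns ``(Trajectory, truth)``
    with the realized duty cycle."""
    rng = np.random.default_rng(config.seed)
    p_lo = config.switching_rate * config.duty_cycle
    p_hi = config.switching_rate * (1.0 - config.duty_cycle)
    low_state = rng.random() < config.duty_cycle
    coords = np.zeros((config.n_frames, 2, 3))
    states = np.zeros(config.n_frames, dtype=bool)
    for f in range(config.n_frames):
        if low_state:
            low_state = rng.random() >= p_hi
        else:
            low_state = rng.random() < p_lo
        states[f] = low_state
        coords[f, 1, 0] = config.low if low_state else config.high
    top = Structure(names=["NZ", "OD1"], elements=["N", "O"],
                    resids=[458, 709], resnames=["LYS", "ASP"],
                    chains=["B", "A"], positions=coords[0])
    traj = Trajectory(topology=top, coordinates=coords)
    truth = {"config": asdict(config), "duty_cycle": float(states.mean())}
    return traj, truth


# --------------------------------------------------------------------------
# dimer toy

@dataclass(frozen=True)
class DimerToyConfig:
    """Two-chain blob dimer: per chain one TM blob and one STAS blob of
    Gaussian-scattered CA pseudo-atoms, with an optional per-frame drift
    applied to chain A's STAS blob."""

    n_atoms_per_blob: int = 30
    blob_sigma: float = 1.5
    tm_center_a: tuple = (12.0, 0.0, 0.0)
    tm_center_b: tuple = (-12.0, 0.0, 0.0)
    stas_center_a: tuple = (6.0, 5.0, -15.0)
    stas_center_b: tuple = (-6.0, -5.0, -15.0)
    drift_per_frame: tuple = (0.0, 0.0, 0.0)   # applied to STAS A
    n_frames: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms_per_blob < 3:
            raise ValueError("blobs need at least 3 atoms")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


def gen_dimer_toy(config: DimerToyConfig):
    """Dimer blob trajectory; returns ``(Trajectory, truth)`` where truth
    carries the exact per-frame STAS centroid of each chain.

    TM atoms get residue numbers in the TM span (45…) and STAS atoms in
    the STAS span (500…), so the default domain definitions resolve.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_atoms_per_blob
    blobs = {}
    for key, center in (("tm_a", config.tm_center_a), ("tm_b", config.tm_center_b),
                        ("stas_a", config.stas_center_a), ("stas_b", config.stas_center_b)):
        cloud = rng.normal(0, config.blob_sigma, (n, 3))
        cloud -= cloud.mean(axis=0)  # exact centroid at the configured center
        blobs[key] = cloud + np.asarray(center, dtype=float)

    def block(chain, resid0):
        return (["CA"] * n, ["C"] * n, list(range(resid0, resid0 + n)),
                ["GLY"] * n, [chain] * n)

    names, elements, resids, resnames, chains = [], [], [], [], []
    for chain, resid0 in (("A", 45), ("A", 500), ("B", 45), ("B", 500)):
        nm, el, ri, rn, ch = block(chain, resid0)
        names += nm; elements += el; resids += ri; resnames += rn; chains += ch
    base = np.vstack([blobs["tm_a"], blobs["stas_a"], blobs["tm_b"], blobs["stas_b"]])
    drift = np.asarray(config.drift_per_frame, dtype=float)
    coords = np.tile(base, (config.n_frames, 1, 1))
    stas_a_slice = slice(n, 2 * n)
    com_a, com_b = [], []
    for f in range(config.n_frames):
        coords[f, stas_a_slice] += f * drift
        com_a.append(coords[f, stas_a_slice].mean(axis=0))
        com_b.append(coords[f, 3 * n:4 * n].mean(axis=0))
    top = Structure(names=names, elements=elements, resids=resids,
                    resnames=resnames, chains=chains, positions=coords[0])
    traj = Trajectory(topology=top, coordinates=coords)
    truth = {"config": asdict(config),
             "stas_com_a": np.asarray(com_a).tolist(),
             "stas_com_b": np.asarray(com_b).tolist()}
    return traj, truth


def write_ground_truth(truth: dict, path) -> None:
    """Sidecar JSON with the generator's ground-truth record."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
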