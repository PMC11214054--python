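"""File I/O: PDB structures, multi-model PDB / DCD trajectories, OpenDX grids.

PDB and DCD parsing/writing is delegated to MDAnalysis behind a thin
adapter that converts to and from the package's own :class:`Structure`
and :class:`Trajectory` containers.  Multi-model PDB is the guaranteed
no-binary fallback for trajectories.  The OpenDX volumetric writer is a
small plain-text emitter compatible with VMD/PyMOL density loading.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .core import MDGateError, Structure, Trajectory

__all__ = [
    "FileFormatError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_opendx",
    "read_opendx",
]


class FileFormatError(MDGateError):
    """A file could not be parsed in its declared format."""


_PDB_SUFFIXES = {".pdb", ".ent"}


def _validate_pdb(path: Path) -> None:
    """Cheap line-level sanity scan so parse errors can name the line.

    Rejects insertion codes (out of scope for author-numbered selections)
    and coordinate fields that do not parse as floats.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FileFormatError(f"{path}: line {lineno}: truncated {rec} record")
            if line[26] not in (" ", ""):
                raise FileFormatError(
                    f"{path}: line {lineno}: insertion code {line[26]!r} not supported")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise FileFormatError(
                    f"{path}: line {lineno}: malformed coordinates in {rec} record") from None


def _cryst1_box(path: Path) -> Optional[np.ndarray]:
    """CRYST1 record from a PDB header (multi-model readers may drop it)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    vals = [float(line[6 + 9 * i:15 + 9 * i]) for i in range(3)]
                    ang = [float(line[33 + 7 * i:40 + 7 * i]) for i in range(3)]
                except ValueError:
                    return None
                box = np.array(vals + ang)
                return box if np.all(box[:3] > 0) else None
            if line.startswith(("ATOM", "HETATM", "MODEL")):
                return None
    return None


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _chains_from(universe) -> np.ndarray:
    atoms = universe.atoms
    try:
        chains = np.asarray(atoms.chainIDs, dtype="U2")
    except Exception:
        chains = np.array([""] * len(atoms), dtype="U2")
    if np.any(chains == ""):
        try:
            segids = np.asarray(atoms.segids, dtype="U2")
        except Exception:
            segids = np.array([""] * len(atoms), dtype="U2")
        chains = np.where(chains == "", segids, chains)
    return np.where(chains == "", "X", chains)


def _elements_from(universe) -> np.ndarray:
    atoms = universe.atoms
    try:
        elements = np.asarray(atoms.elements, dtype="U2")
        if np.all(elements != ""):
            return elements
    except Exception:
        elements = np.array([""] * len(atoms), dtype="U2")
    names = np.asarray(atoms.names, dtype="U6")
    guessed = []
    for el, name in zip(elements, names):
        if el:
            guessed.append(el)
        else:
            guessed.append(next((c for c in name if c.isalpha()), "C").upper())
    return np.asarray(guessed, dtype="U2")


def _box_from(dimensions) -> Optional[np.ndarray]:
    if dimensions is None:
        return None
    box = np.asarray(dimensions, dtype=float)
    if box.shape != (6,) or np.any(box[:3] <= 0):
        return None
    return box


def read_structure(path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model).

    ATOM records are retained with author residue numbering.  A file with
    only HETATM records (e.g. waters) is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _PDB_SUFFIXES:
        _validate_pdb(path)
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as err:  # noqa: BLE001 - re-raise as format error
        raise FileFormatError(f"failed to parse {path}: {err}") from err
    if len(u.atoms) == 0:
        raise FileFormatError(f"{path}: empty structure")
    try:
        record_types = np.asarray(u.atoms.record_types)
        if np.all(record_types == "HETATM"):
            raise FileFormatError(f"{path}: no protein atoms (only HETATM records)")
    except AttributeError:
        pass
    return Structure(
        names=np.asarray(u.atoms.names, dtype="U6"),
        elements=_elements_from(u),
        resids=np.asarray(u.atoms.resids, dtype=int),
        resnames=np.asarray(u.atoms.resnames, dtype="U4"),
        chains=_chains_from(u),
        positions=np.asarray(u.atoms.positions, dtype=float),
        box=_box_from(u.dimensions) if _box_from(u.dimensions) is not None
        else (_cryst1_box(path) if path.suffix.lower() in _PDB_SUFFIXES else None),
    )


def read_trajectory(path, topology: Structure) -> Trajectory:
    """Read a multi-frame trajectory (multi-model PDB, or DCD/XTC/TRR).

    The frame atom count must match ``topology``; positions come back in Å
    with per-frame boxes and times (ps) where the format stores them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mda = _import_mda()
    n = topology.n_atoms
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if path.suffix.lower() in _PDB_SUFFIXES:
                _validate_pdb(path)
                u = mda.Universe(str(path))
            else:
                u = mda.Universe.empty(n, trajectory=True)
                u.load_new(str(path))
    except FileFormatError:
        raise
    except Exception as err:  # noqa: BLE001
        raise FileFormatError(f"failed to read trajectory {path}: {err}") from err
    if len(u.atoms) != n:
        raise MDGateError(
            f"trajectory {path} has {len(u.atoms)} atoms per frame "
            f"but topology has {n}")
    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            boxes.append(_box_from(ts.dimensions))
            times.append(float(ts.time) if ts.time is not None else float(ts.frame))
    times = np.asarray(times)
    if np.any(np.diff(times) < 0):
        times = np.arange(len(coords), dtype=float)
    box_arr = None
    if all(b is not None for b in boxes):
        box_arr = np.asarray(boxes)
    elif path.suffix.lower() in _PDB_SUFFIXES:
        header_box = _cryst1_box(path)
        if header_box is not None:
            box_arr = np.tile(header_box, (len(coords), 1))
    return Trajectory(topology=topology, coordinates=np.asarray(coords),
                      boxes=box_arr, times=times)


def _to_universe(structure: Structure, coordinates: np.ndarray,
                 boxes: Optional[np.ndarray]):
    """Build an in-memory MDAnalysis Universe mirroring a Structure."""
    mda = _import_mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    keys = list(dict.fromkeys(zip(structure.chains, structure.resids)))
    res_index = {k: i for i, k in enumerate(keys)}
    atom_resindex = np.array([res_index[(c, r)] for c, r in
                              zip(structure.chains, structure.resids)])
    res_chain = np.array([k[0] for k in keys], dtype="U2")
    seg_ids = list(dict.fromkeys(res_chain))
    seg_index = {s: i for i, s in enumerate(seg_ids)}
    residue_segindex = np.array([seg_index[c] for c in res_chain])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(structure.n_atoms, n_residues=len(keys),
                               n_segments=len(seg_ids),
                               atom_resindex=atom_resindex,
                               residue_segindex=residue_segindex,
                               trajectory=False)
        u.add_TopologyAttr("names", structure.names)
        u.add_TopologyAttr("elements", structure.elements)
        u.add_TopologyAttr("chainIDs", structure.chains)
        u.add_TopologyAttr("resids", [int(k[1]) for k in keys])
        first_atom = {res_index[(c, r)]: rn for c, r, rn in
                      zip(structure.chains[::-1], structure.resids[::-1],
                          structure.resnames[::-1])}
        u.add_TopologyAttr("resnames", [first_atom[i] for i in range(len(keys))])
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("occupancies", np.ones(structure.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(structure.n_atoms))
        coords = np.asarray(coordinates, dtype=np.float32)
        if coords.ndim == 2:
            coords = coords[None]
        dims = None
        if boxes is not None:
            dims = np.asarray(boxes, dtype=np.float32)
            if dims.ndim == 1:
                dims = np.tile(dims, (coords.shape[0], 1))
        u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB."""
    boxes = structure.box
    u = _to_universe(structure, structure.positions, boxes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (or DCD if the suffix says so)."""
    path = Path(path)
    boxes = traj.boxes
    if boxes is None and traj.topology.box is not None:
        boxes = np.tile(traj.topology.box, (traj.n_frames, 1))
    u = _to_universe(traj.topology, traj.coordinates, boxes)
    mda = _import_mda()
    multiframe = path.suffix.lower() in _PDB_SUFFIXES
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms,
                        multiframe=True if multiframe else None) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def write_opendx(values: np.ndarray, origin, spacing: float, path,
                 comment: str = "mdgate occupancy grid") -> None:
    """Write a scalar grid in OpenDX format (z fastest, C order)."""
    values = np.asarray(values, dtype=float)
    nx, ny, nz = values.shape
    ox, oy, oz = np.asarray(origin, dtype=float)
    flat = values.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_opendx(path):
    """Read a grid written by :func:`write_opendx`; returns (values, origin, spacing)."""
    origin = None
    deltas = []
    counts = None
    data = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            t = line.split()
            if not t or t[0] == "#":
                continue
            if t[0] == "object" and "gridpositions" in line:
                counts = tuple(int(x) for x in t[-3:])
            elif t[0] == "origin":
                origin = np.array([float(x) for x in t[1:4]])
            elif t[0] == "delta":
                deltas.append([float(x) for x in t[1:4]])
            elif t[0] == "object" and "class array" in line:
                n_items = int(t[t.index("items") + 1])
            elif n_items is not None and len(data) < n_items:
                try:
                    data.extend(float(x) for x in t)
                except ValueError:
                    pass
    if counts is None or origin is None or n_items is None:
        raise FileFormatError(f"{path}: not a recognizable OpenDX grid")
    values = np.asarray(data[:n_items]).reshape(counts, order="C")
    spacing = float(deltas[0][0]) if deltas else 1.0
    return values, origin, spacing
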