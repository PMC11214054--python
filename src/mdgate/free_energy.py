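"""Event-conditioned free-energy landscapes by Boltzmann inversion.

For an arbitrary 1D/2D reaction coordinate, frames where an "objective
event" occurred (ion bound, dihedral pair inside a cell, ...) are binned
on a regular grid and inverted to relative free energies

    ΔG_i = −R T ln(n_i / n_min)

where n_i is the event count in cell i and n_min the smallest nonzero
count, so the landscape's zero sits at the rarest visited cell and all
defined values are ≤ 0.  "ln" is the natural logarithm (Boltzmann
inversion convention).  Cells with n_i = 0 are masked, never imputed.

The dual-mode dihedral-correlation classifier probes a (φ, ψ) landscape
at three fixed points and requires the free energy to be strictly below
a threshold (default −0.9 kcal/mol) at all of them; a masked probe cell
fails the test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MDGateError

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_PROBES",
    "DUAL_MODE_THRESHOLD",
    "AxisSpec",
    "ReactionCoordinateSpec",
    "EventCounter",
    "FreeEnergyLandscape",
    "DualModeResult",
    "NoEventsError",
    "count_events",
    "free_energy",
    "check_nmin_convention",
    "binding_distance_landscape",
    "dihedral_landscape",
    "dual_mode_classify",
]

R_KCAL_PER_MOL_K = 1.98720425e-3     # gas constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE = 303.15         # K, simulation thermostat setting
DEFAULT_DISTANCE_INTERVAL = 0.25     # Å
DEFAULT_DIHEDRAL_INTERVAL = 1.0      # degrees
DEFAULT_PROBES = ((-60.0, 15.0), (-60.0, -45.0), (-90.0, -15.0))  # (φ, ψ)
DUAL_MODE_THRESHOLD = -0.9           # kcal/mol


class NoEventsError(MDGateError):
    """No frame carried the objective event."""


@dataclass
class AxisSpec:
    """One reaction-coordinate axis with a regular bin grid.

    Distance axes are anchored at the axis minimum (``origin`` resolved at
    binning time unless given); periodic dihedral axes span (−180°, 180°]
    anchored at −180°.  Bins are half-open [lo, hi).
    """

    name: str
    units: str = "A"                  # "A" or "deg"
    interval: float = DEFAULT_DISTANCE_INTERVAL
    periodic: bool = False
    origin: Optional[float] = None
    nbins: Optional[int] = None

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError(f"axis {self.name}: interval must be positive")
        if self.periodic:
            self.origin = -180.0
            self.nbins = int(round(360.0 / self.interval))

    def resolve(self, values: np.ndarray) -> "AxisSpec":
        if self.periodic or (self.origin is not None and self.nbins is not None):
            return self
        origin = float(np.min(values)) if self.origin is None else self.origin
        span = float(np.max(values)) - origin
        nbins = max(int(np.floor(span / self.interval + 1e-9)) + 1, 1)
        return AxisSpec(self.name, self.units, self.interval, False, origin, nbins)

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.periodic:
            v = np.mod(v + 180.0, 360.0) - 180.0  # into (-180, 180]
            idx = np.floor((v - self.origin) / self.interval).astype(int)
            return np.mod(idx, self.nbins)
        return np.floor((v - self.origin) / self.interval).astype(int)

    def centers(self) -> np.ndarray:
        return self.origin + (np.arange(self.nbins) + 0.5) * self.interval


def dihedral_axis(name: str, interval: float = DEFAULT_DIHEDRAL_INTERVAL) -> AxisSpec:
    return AxisSpec(name, units="deg", interval=interval, periodic=True)


@dataclass
class ReactionCoordinateSpec:
    """1D or 2D reaction coordinate: an ordered list of axes."""

    axes: Sequence[AxisSpec]

    def __post_init__(self):
        self.axes = list(self.axes)
        if len(self.axes) not in (1, 2):
            raise ValueError("reaction coordinate must be 1D or 2D")

    @property
    def ndim(self) -> int:
        return len(self.axes)


@dataclass
class EventCounter:
    """Per-cell counts of the objective event on a reaction-coordinate grid."""

    counts: np.ndarray
    axes: Sequence[AxisSpec]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_min(self) -> int:
        nz = self.counts[self.counts > 0]
        if nz.size == 0:
            raise NoEventsError("no events counted")
        return int(nz.min())


@dataclass
class FreeEnergyLandscape:
    """ΔG_i (kcal/mol) on the reaction-coordinate grid; empty cells masked."""

    dG: np.ma.MaskedArray
    counts: np.ndarray
    axes: Sequence[AxisSpec]
    temperature: float
    n_min: int

    def cell_index(self, point) -> tuple:
        """Grid cell containing a point; errors if outside non-periodic bounds."""
        point = np.atleast_1d(np.asarray(point, dtype=float))
        if point.shape != (len(self.axes),):
            raise ValueError(f"point must have {len(self.axes)} coordinates")
        idx = []
        for ax, v in zip(self.axes, point):
            i = int(ax.bin_index(np.array([v]))[0])
            if not ax.periodic and not (0 <= i < ax.nbins):
                raise MDGateError(
                    f"probe {v} {ax.units} outside the landscape bounds on axis {ax.name}")
            idx.append(i)
        return tuple(idx)

    def value_at(self, point) -> float:
        """ΔG of the cell containing ``point``; NaN when the cell is masked."""
        idx = self.cell_index(point)
        v = self.dG[idx]
        return float("nan") if np.ma.is_masked(v) else float(v)

    def to_frame(self) -> pd.DataFrame:
        grids = np.meshgrid(*[ax.centers() for ax in self.axes], indexing="ij")
        data = {ax.name: g.ravel() for ax, g in zip(self.axes, grids)}
        data["n"] = self.counts.ravel()
        dg = self.dG.filled(np.nan).ravel()
        data["dG_kcal_mol"] = dg
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def metadata(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "n_min": self.n_min,
            "total_events": int(self.counts.sum()),
            "axes": [{"name": ax.name, "units": ax.units, "interval": ax.interval,
                      "periodic": ax.periodic, "origin": ax.origin, "nbins": ax.nbins}
                     for ax in self.axes],
        }


@dataclass
class DualModeResult:
    dual_mode: bool
    probe_points: tuple
    probe_values: tuple
    threshold: float

    def to_json(self, chain: Optional[str] = None) -> str:
        d = {"dual_mode": bool(self.dual_mode),
             "threshold_kcal_mol": self.threshold,
             "probes": [{"phi": p[0], "psi": p[1],
                         "dG_kcal_mol": None if v != v else v}
                        for p, v in zip(self.probe_points, self.probe_values)]}
        if chain is not None:
            d = {"chain": chain, **d}
        return json.dumps(d)


def count_events(rc_values, event_flags, spec: ReactionCoordinateSpec) -> EventCounter:
    """Bin flagged frames on the reaction-coordinate grid.

    ``rc_values`` is (n,) for 1D or (n, 2) for 2D; a frame contributes to
    the cell containing its coordinates iff its flag is true.  Periodic
    axes are binned modulo 360°.
    """
    vals = np.asarray(rc_values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    flags = np.asarray(event_flags, dtype=bool)
    if vals.shape[0] != flags.shape[0] or vals.shape[0] == 0:
        raise ValueError("rc_values and event_flags must have equal nonzero length")
    if vals.shape[1] != spec.ndim:
        raise ValueError(f"rc_values has {vals.shape[1]} columns for a {spec.ndim}D spec")
    if not flags.any():
        raise NoEventsError("no events: all event flags are false")
    axes = [ax.resolve(vals[:, k]) for k, ax in enumerate(spec.axes)]
    dims = tuple(ax.nbins for ax in axes)
    counts = np.zeros(dims, dtype=np.int64)
    sel = vals[flags]
    idx = [ax.bin_index(sel[:, k]) for k, ax in enumerate(axes)]
    ok = np.ones(sel.shape[0], dtype=bool)
    for k, ax in enumerate(axes):
        ok &= (idx[k] >= 0) & (idx[k] < ax.nbins)
    flat = np.ravel_multi_index(tuple(i[ok] for i in idx), dims)
    np.add.at(counts.reshape(-1), flat, 1)
    return EventCounter(counts=counts, axes=axes)


def free_energy(counter: EventCounter,
                temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergyLandscape:
    """Boltzmann inversion ΔG_i = −RT ln(n_i/n_min) of an event counter."""
    if temperature <= 0:
        raise MDGateError(f"temperature must be positive, got {temperature}")
    n_min = counter.n_min
    counts = counter.counts
    with np.errstate(divide="ignore"):
        dg = -R_KCAL_PER_MOL_K * temperature * np.log(counts / n_min)
    dG = np.ma.masked_array(dg, mask=(counts == 0))
    return FreeEnergyLandscape(dG=dG, counts=counts, axes=list(counter.axes),
                               temperature=temperature, n_min=n_min)


@dataclass
class NminDiagnostic:
    n_min: int
    ok: bool
    message: str


def check_nmin_convention(counter: EventCounter) -> NminDiagnostic:
    """Report whether the landscape zero is pinned at singly-visited cells.

    The estimator's reference convention sets the grid interval fine enough
    that n_min = 1; a larger n_min shifts the whole landscape and a
    warning advises refining the interval.
    """
    n_min = counter.n_min
    if n_min == 1:
        return NminDiagnostic(1, True, "n_min = 1: reference convention satisfied")
    msg = (f"n_min = {n_min} != 1; consider a finer grid interval so the "
           "rarest visited cell is singly visited")
    warnings.warn(msg, stacklevel=2)
    return NminDiagnostic(n_min, False, msg)


def binding_distance_landscape(distances, bound_flags,
                               interval: float = DEFAULT_DISTANCE_INTERVAL,
                               temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergyLandscape:
    """Free energy of ion binding versus a 1D distance coordinate.

    ``bound_flags`` may be booleans or the per-frame bound-ion counts from
    the occupancy time series (any count > 0 is an event).
    """
    flags = np.asarray(bound_flags)
    if flags.dtype != bool:
        flags = flags > 0
    spec = ReactionCoordinateSpec([AxisSpec("distance", "A", interval)])
    return free_energy(count_events(np.asarray(distances, dtype=float), flags, spec),
                       temperature)


def dihedral_landscape(phi, psi, interval: float = DEFAULT_DIHEDRAL_INTERVAL,
                       temperature: float = DEFAULT_TEMPERATURE,
                       event_flags=None) -> FreeEnergyLandscape:
    """(φ, ψ) free-energy landscape; with all-true flags this is the
    Boltzmann-inverted occupancy histogram of the dihedral pair."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    flags = np.ones(len(phi), dtype=bool) if event_flags is None else event_flags
    spec = ReactionCoordinateSpec([dihedral_axis("phi", interval),
                                   dihedral_axis("psi", interval)])
    return free_energy(count_events(np.column_stack([phi, psi]), flags, spec),
                       temperature)


def dual_mode_classify(landscape: FreeEnergyLandscape,
                       probes: Sequence = DEFAULT_PROBES,
                       threshold: float = DUAL_MODE_THRESHOLD) -> DualModeResult:
    """Dual-mode (crankshaft + non-crankshaft) dihedral-correlation call.

    ΔG is evaluated at the cell containing each probe (no interpolation);
    dual mode requires every probe strictly below the threshold.  A masked
    (unvisited) probe cell fails.
    """
    if len(landscape.axes) != 2:
        raise MDGateError("dual-mode classification needs a 2D (phi, psi) landscape")
    values = tuple(landscape.value_at(p) for p in probes)
    dual = all((v == v) and (v < threshold) for v in values)  # NaN fails
    return DualModeResult(dual_mode=dual, probe_points=tuple(tuple(p) for p in probes),
                          probe_values=values, threshold=threshold)
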