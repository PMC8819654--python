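"""Molecular and collective dipole moments.

Containers for topology/trajectory data and the dipole operations used by
every analysis stage: per-molecule dipoles (Σ q_i·r_i, reported in Debye),
collective group dipoles, and dipole time series for the protein, each
hydration sub-shell, and bulk water.

For neutral molecules the dipole is origin-independent; the protein carries
a net charge (+8 e for hen egg-white lysozyme at pH 7), so its dipole is
evaluated about the molecular centre of mass, which makes the reported value
translation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._units import E_ANGSTROM_TO_DEBYE

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "DipoleSeries",
    "molecular_dipole",
    "collective_dipole_component",
    "dipole_series",
    "unwrap_molecule",
]

PROTEIN, WATER, ION = "protein", "water", "ion"

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Topology:
    """Per-site charges/masses and molecule groupings.

    Arrays are indexed by site; ``mol_id`` maps each site to a 0-based
    molecule index, and ``mol_class`` (length n_molecules) labels each
    molecule ``protein``, ``water`` or ``ion``.
    """

    charges: np.ndarray
    masses: np.ndarray
    mol_id: np.ndarray
    mol_class: np.ndarray

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.mol_id = np.asarray(self.mol_id, dtype=int)
        self.mol_class = np.asarray(self.mol_class, dtype=object)
        n = self.charges.shape[0]
        if not (self.masses.shape[0] == n == self.mol_id.shape[0]):
            raise ValueError("charges, masses and mol_id must have equal length")
        if self.mol_id.min(initial=0) < 0 or (
            n and self.mol_id.max() >= len(self.mol_class)
        ):
            raise ValueError("mol_id refers to molecules outside mol_class")
        bad = [c for c in set(self.mol_class) if c not in (PROTEIN, WATER, ION)]
        if bad:
            raise ValueError(f"unknown molecule classes: {bad}")
        for m in self.molecules_of_class(WATER):
            q = self.charges[self.sites_of(m)].sum()
            if abs(q) > 1e-9:
                raise ValueError(f"water molecule {m} is not electroneutral (q={q})")

    @property
    def n_sites(self) -> int:
        return self.charges.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.mol_class)

    def sites_of(self, mol: int) -> np.ndarray:
        return np.flatnonzero(self.mol_id == mol)

    def molecules_of_class(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.mol_class == cls)

    def protein_sites(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.mol_id, self.molecules_of_class(PROTEIN)))

    def protein_heavy_sites(self, min_mass: float = 3.0) -> np.ndarray:
        """Protein heavy atoms (mass above ``min_mass`` g/mol excludes H)."""
        sites = self.protein_sites()
        return sites[self.masses[sites] > min_mass]

    def water_oxygen_sites(self) -> np.ndarray:
        """Heaviest site of each water molecule, in water-molecule order."""
        out = []
        for m in self.molecules_of_class(WATER):
            sites = self.sites_of(m)
            out.append(sites[np.argmax(self.masses[sites])])
        return np.asarray(out, dtype=int)


@dataclass
class Frame:
    """One trajectory frame: positions (Å), rectangular box lengths (Å), time (ps)."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive rectangular lengths")


@dataclass
class Trajectory:
    """Ordered frames with uniform time spacing.

    times in ps, positions with shape (n_frames, n_sites, 3) in Å, box with
    shape (n_frames, 3) in Å (rectangular periodic cell).
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_sites, 3)")
        if len(self.times) != self.positions.shape[0] or self.box.shape != (
            len(self.times),
            3,
        ):
            raise ValueError("times, positions and box frame counts disagree")
        dts = np.diff(self.times)
        if len(dts) and dts.min() <= 0:
            i = int(np.argmax(dts <= 0))
            raise ValueError(f"times must be strictly increasing (frame {i + 1})")
        if len(dts) > 1 and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            i = int(np.argmax(~np.isclose(dts, dts[0], rtol=1e-6, atol=1e-9)))
            raise ValueError(f"non-uniform time spacing at frame {i + 1}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.positions[i], self.box[i])


@dataclass
class DipoleSeries:
    """Collective dipole x-component time series (Debye) for a named group."""

    group: str
    times: np.ndarray
    dipole_x: np.ndarray
    vectors: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dipole_x = np.asarray(self.dipole_x, dtype=float)
        if self.times.shape != self.dipole_x.shape:
            raise ValueError("times and dipole_x must have equal length")
        if not np.all(np.isfinite(self.dipole_x)):
            raise ValueError("dipole series contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def unwrap_molecule(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a molecule whole across periodic boundaries.

    Each site is shifted by the minimum-image convention relative to the
    first site; adequate for compact molecules smaller than half the box.
    """
    ref = positions[0]
    d = positions - ref
    d -= box * np.round(d / box)
    return ref + d


def molecular_dipole(positions: np.ndarray, charges: np.ndarray) -> np.ndarray:
    """Dipole vector μ = Σ q_i·r_i of one molecule, in Debye.

    Positions must already be unwrapped (molecule whole); for a neutral
    molecule the result is independent of the coordinate origin.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    return E_ANGSTROM_TO_DEBYE * charges @ positions


def _group_molecules(topology: Topology, group) -> np.ndarray:
    if isinstance(group, str):
        if group == PROTEIN:
            mols = topology.molecules_of_class(PROTEIN)
        else:
            raise ValueError(
                f"unresolved group {group!r}: shell groups need an explicit "
                "molecule list (see dipole_series / ShellAssignment)"
            )
    else:
        mols = np.asarray(list(group), dtype=int)
    if len(mols) == 0 and isinstance(group, str):
        raise ValueError(f"no molecules in group {group!r}")
    return mols


def collective_dipole_component(
    frame: Frame, topology: Topology, group, axis: str = "x"
) -> float:
    """Collective dipole component (Debye) of a group in one frame.

    ``group`` is ``"protein"`` or an iterable of molecule indices (e.g. the
    waters of one hydration sub-shell). Water groups sum per-molecule
    dipoles; a net-charged group (the protein) uses Σ q_i·(r_i − R_com)
    about its centre of mass so the value is translation-invariant.
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    mols = _group_molecules(topology, group)
    total = np.zeros(3)
    for m in mols:
        sites = topology.sites_of(int(m))
        pos = unwrap_molecule(frame.positions[sites], frame.box)
        q = topology.charges[sites]
        net = q.sum()
        if abs(net) > 1e-9:
            masses = topology.masses[sites]
            com = masses @ pos / masses.sum()
            total += E_ANGSTROM_TO_DEBYE * (q @ (pos - com))
        else:
            total += molecular_dipole(pos, q)
    return float(total[ax])


def dipole_series(
    trajectory: Trajectory,
    topology: Topology,
    assignments: Optional[Sequence] = None,
    group: str = PROTEIN,
    axis: str = "x",
) -> DipoleSeries:
    """Per-frame collective dipole component for a named group.

    For shell groups (``shell1``, ``shell2``, ``bulk``) the per-frame
    membership is taken from ``assignments`` (one ShellAssignment per
    frame); waters may migrate between shells from frame to frame. Ions are
    excluded from all groups.
    """
    values = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        fr = trajectory.frame(i)
        if group == PROTEIN:
            members = PROTEIN
        else:
            if assignments is None:
                raise ValueError("shell groups require per-frame shell assignments")
            members = assignments[i].molecules_in(group)
        values[i] = collective_dipole_component(fr, topology, members, axis=axis)
    return DipoleSeries(group=group, times=trajectory.times.copy(), dipole_x=values)
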