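"""Hydration sub-shell decomposition around the protein surface.

Waters are classified by the minimum-image distance of their oxygen from
the nearest protein heavy atom: the first sub-shell within 2.25 Å of the
surface, a second sub-shell out to 6 Å where the water density has relaxed
to the 1 g/cm³ bulk value, and bulk beyond. Per-molecule volumes come from
a periodic Voronoi tessellation seeded at water oxygens plus protein heavy
atoms, so protein volume is excluded from water cells and the cells of all
molecules partition the box exactly. The same machinery yields
Voronoi-normalized density profiles and the distribution of the protein's
intrinsic electrostatic field at hydration-water positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, Voronoi, cKDTree

from ._units import (
    AVOGADRO,
    COULOMB_V_ANGSTROM_PER_E,
    WATER_MOLAR_MASS,
)
from .dipoles import Frame, Topology, Trajectory

__all__ = [
    "SHELL1",
    "SHELL2",
    "BULK",
    "ShellAssignment",
    "DensityProfile",
    "surface_distance",
    "assign_shells",
    "periodic_voronoi_volumes",
    "voronoi_shell_volumes",
    "density_profile",
    "intrinsic_field_distribution",
]

logger = logging.getLogger(__name__)

SHELL1, SHELL2, BULK = "shell1", "shell2", "bulk"

DEFAULT_B1 = 2.25  # Å, outer edge of the first hydration sub-shell
DEFAULT_B2 = 6.0   # Å, distance at which water density reaches bulk


@dataclass
class ShellAssignment:
    """Per-frame water→shell labels with surface distances and volumes."""

    frame_time: float
    water_mols: np.ndarray        # molecule indices, one per water
    surface_distances: np.ndarray  # Å
    labels: np.ndarray             # 'shell1' | 'shell2' | 'bulk'
    voronoi_volumes: Optional[np.ndarray] = None  # Å³ per water

    def molecules_in(self, shell: str) -> np.ndarray:
        if shell not in (SHELL1, SHELL2, BULK):
            raise ValueError(f"unknown shell {shell!r}")
        return self.water_mols[self.labels == shell]

    def counts(self) -> dict:
        return {s: int((self.labels == s).sum()) for s in (SHELL1, SHELL2, BULK)}


@dataclass
class DensityProfile:
    """Water mass density (g/cm³) vs distance from the protein surface.

    ``counts`` and ``volumes`` hold the per-bin accumulated water counts and
    Voronoi volumes (Å³) over all frames, so profiles can be pooled (counts
    and volumes add) for better-conditioned far-field estimates.
    """

    bin_edges: np.ndarray  # Å
    density: np.ndarray    # g/cm³ per bin
    counts: Optional[np.ndarray] = None
    volumes: Optional[np.ndarray] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def pooled_density(self, min_distance: float = 0.0) -> float:
        """Mass-weighted density over all bins at/beyond ``min_distance``."""
        if self.counts is None or self.volumes is None:
            raise ValueError("profile carries no counts/volumes to pool")
        sel = self.bin_centers >= min_distance
        vol = self.volumes[sel].sum()
        if vol == 0:
            return 0.0
        mass = self.counts[sel].sum() * WATER_MOLAR_MASS / AVOGADRO
        return float(mass / (vol * 1e-24))


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def surface_distance(frame: Frame, topology: Topology, water_mol: int) -> float:
    """Minimum-image distance (Å) from a water's oxygen to the protein surface.

    The surface is the set of protein heavy atoms; the distance is the
    minimum over them.
    """
    heavy = topology.protein_heavy_sites()
    if len(heavy) == 0:
        raise ValueError("topology contains no protein heavy atoms")
    oxygens = topology.water_oxygen_sites()
    waters = topology.molecules_of_class("water")
    o_site = oxygens[np.flatnonzero(waters == water_mol)[0]]
    d = _min_image(frame.positions[heavy] - frame.positions[o_site], frame.box)
    return float(np.sqrt((d**2).sum(axis=1)).min())


def _all_surface_distances(frame: Frame, topology: Topology) -> Tuple[np.ndarray, np.ndarray]:
    heavy = topology.protein_heavy_sites()
    if len(heavy) == 0:
        raise ValueError("topology contains no protein heavy atoms")
    waters = topology.molecules_of_class("water")
    oxy = topology.water_oxygen_sites()
    d = frame.positions[oxy][:, None, :] - frame.positions[heavy][None, :, :]
    d = _min_image(d, frame.box)
    dist = np.sqrt((d**2).sum(axis=2)).min(axis=1)
    return waters, dist


def assign_shells(
    frame: Frame,
    topology: Topology,
    b1: float = DEFAULT_B1,
    b2: float = DEFAULT_B2,
) -> ShellAssignment:
    """Partition every water into shell1 (d ≤ b1), shell2 (b1 < d ≤ b2) or bulk."""
    if not 0 < b1 < b2:
        raise ValueError("shell boundaries must satisfy 0 < b1 < b2")
    waters, dist = _all_surface_distances(frame, topology)
    labels = np.where(dist <= b1, SHELL1, np.where(dist <= b2, SHELL2, BULK))
    return ShellAssignment(
        frame_time=frame.time,
        water_mols=waters,
        surface_distances=dist,
        labels=labels.astype(object),
    )


def periodic_voronoi_volumes(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Voronoi cell volume (Å³) of each seed in a rectangular periodic box.

    Seeds are wrapped into the box and surrounded by their 26 periodic
    images so every central cell is bounded; volumes are convex-hull
    volumes of the cell vertices. The cells partition the box, so the
    volumes sum to the box volume (asserted by callers to 0.1%).
    """
    points = np.asarray(points, dtype=float) % box
    n = len(points)
    dup = cKDTree(points, boxsize=box).query_pairs(1e-9)
    if dup:
        pairs = sorted(dup)[:5]
        raise ValueError(f"degenerate (coincident) Voronoi seeds: {pairs}")
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)]
    )
    images = (points[None, :, :] + shifts[:, None, :] * box).reshape(-1, 3)
    vor = Voronoi(np.vstack([points, images]))
    volumes = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            raise ValueError(f"unbounded Voronoi cell for seed {i}")
        volumes[i] = ConvexHull(vor.vertices[region]).volume
    return volumes


def voronoi_shell_volumes(
    frame: Frame, topology: Topology, assignment: ShellAssignment
) -> dict:
    """Total Voronoi volume (Å³) of each hydration sub-shell.

    The tessellation is seeded at water oxygens plus protein heavy atoms
    (so protein volume is not attributed to water); a shell's volume is the
    sum of its member waters' cells. Fills ``assignment.voronoi_volumes``.
    """
    heavy = topology.protein_heavy_sites()
    oxy = topology.water_oxygen_sites()
    seeds = np.vstack([frame.positions[oxy], frame.positions[heavy]])
    volumes = periodic_voronoi_volumes(seeds, frame.box)
    box_volume = float(np.prod(frame.box))
    if abs(volumes.sum() - box_volume) > 1e-3 * box_volume:
        raise AssertionError(
            f"tessellation lost volume: {volumes.sum():.3f} vs box {box_volume:.3f}"
        )
    water_vol = volumes[: len(oxy)]
    assignment.voronoi_volumes = water_vol
    return {s: float(water_vol[assignment.labels == s].sum()) for s in (SHELL1, SHELL2, BULK)}


def density_profile(
    trajectory: Trajectory,
    topology: Topology,
    bin_width: float = 0.1,
    max_distance: float = 12.0,
) -> DensityProfile:
    """Water density (g/cm³) vs surface distance, Voronoi-normalized.

    Each bin's density is (water mass in bin)/(sum of the Voronoi cell
    volumes of the waters in the bin), accumulated over frames. Empty bins
    report zero density. One water weighs 18.0153 g/mol.
    """
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    mass_per_water = WATER_MOLAR_MASS / AVOGADRO  # g
    counts = np.zeros(len(edges) - 1)
    volumes = np.zeros(len(edges) - 1)
    heavy = topology.protein_heavy_sites()
    oxy = topology.water_oxygen_sites()
    for i in range(trajectory.n_frames):
        frame = trajectory.frame(i)
        _, dist = _all_surface_distances(frame, topology)
        seeds = np.vstack([frame.positions[oxy], frame.positions[heavy]])
        vol = periodic_voronoi_volumes(seeds, frame.box)[: len(oxy)]
        idx = np.digitize(dist, edges) - 1
        ok = (idx >= 0) & (idx < len(counts))
        np.add.at(counts, idx[ok], 1.0)
        np.add.at(volumes, idx[ok], vol[ok])
    density = np.zeros_like(counts)
    nz = volumes > 0
    # Å³ → cm³ is 1e-24
    density[nz] = counts[nz] * mass_per_water / (volumes[nz] * 1e-24)
    return DensityProfile(bin_edges=edges, density=density, counts=counts,
                          volumes=volumes)


def intrinsic_field_distribution(
    frame: Frame,
    topology: Topology,
    assignment: ShellAssignment,
    bins: int = 50,
    range_v_per_ang: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribution of the protein's Coulomb field over hydration waters.

    At each hydration-layer (shell1 ∪ shell2) water-oxygen position r, the
    field is the bare minimum-image Coulomb sum over all protein partial
    charges, E(r) = Σ k_C·q_i·(r−r_i)/|r−r_i|³ with k_C = 14.3996 V·Å/e
    (no cutoff, no Ewald — a local-field diagnostic).

    Returns ``(magnitudes, hist, bin_edges)`` where ``hist`` is the
    probability density of |E| in V/Å.
    """
    prot = topology.protein_sites()
    prot = prot[np.abs(topology.charges[prot]) > 0]
    hydration = np.concatenate(
        [assignment.molecules_in(SHELL1), assignment.molecules_in(SHELL2)]
    )
    waters = topology.molecules_of_class("water")
    oxy = topology.water_oxygen_sites()
    o_sites = oxy[np.isin(waters, hydration)]

    mags = []
    for s in o_sites:
        if len(prot) == 0:
            mags.append(0.0)
            continue
        d = _min_image(frame.positions[s] - frame.positions[prot], frame.box)
        r2 = (d**2).sum(axis=1)
        if r2.min() < 1e-12:
            logger.warning(
                "evaluation point %d coincides with a protein charge; excluded", s
            )
            continue
        e = COULOMB_V_ANGSTROM_PER_E * (
            (topology.charges[prot] / r2**1.5)[:, None] * d
        ).sum(axis=0)
        mags.append(np.linalg.norm(e))
    mags = np.asarray(mags)
    hist, edges = np.histogram(mags, bins=bins, range=range_v_per_ang, density=True)
    return mags, hist, edges


def coulomb_field(
    point: np.ndarray, charge_positions: np.ndarray, charges: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Bare minimum-image Coulomb field (V/Å) at one point from point charges."""
    d = _min_image(np.asarray(point) - np.asarray(charge_positions), box)
    r2 = (d**2).sum(axis=1)
    if len(r2) == 0:
        return np.zeros(3)
    if r2.min() < 1e-12:
        raise ValueError("evaluation point coincides with a charge")
    return COULOMB_V_ANGSTROM_PER_E * ((charges / r2**1.5)[:, None] * d).sum(axis=0)
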