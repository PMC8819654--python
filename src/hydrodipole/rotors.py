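"""Synthetic dipole-rotor ensembles with closed-form ground truth.

Generates orientation trajectories of non-interacting point dipoles
undergoing overdamped rotational Brownian motion (Euler–Maruyama on the
unit sphere) under an applied field and, optionally, a per-rotor static
"intrinsic" field that emulates the binding environment of first-shell
hydration water. The model deliberately freezes translation: it preserves
exactly the observables the analysis stages measure — dipole alignment
(Langevin function), orientational relaxation (exp(−2·D_r·t)) and the
Debye phase lag arctan(ωτ)/ω — with analytic oracles for each.

Also provides ``emit_trajectory``, which renders an orientation series as a
3-site water-like coordinate trajectory so the full coordinate-space
pipeline (shells → dipoles → relaxation → lag) can be exercised end to end,
and ``uniform_water_box`` for density/tessellation fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._units import (
    DEBYE_V_PER_ANGSTROM_TO_EV,
    E_ANGSTROM_TO_DEBYE,
    thermal_energy_ev,
)
from .dipoles import Topology, Trajectory
from .field import FieldSpec, field_at, rms_to_max

__all__ = [
    "RotorEnsembleConfig",
    "OrientationSeries",
    "simulate_ensemble",
    "langevin_alignment",
    "debye_lag",
    "emit_trajectory",
    "uniform_water_box",
]

# TIP-style rigid water geometry used when rendering rotors as molecules
_OH_BOND = 0.9572  # Å
_HALF_HOH = math.radians(52.26)


@dataclass
class RotorEnsembleConfig:
    """Ensemble of independent Brownian rotors.

    Parameters
    ----------
    n_rotors:
        Ensemble size.
    mu:
        Dipole magnitude in Debye.
    d_rot:
        Rotational diffusion coefficient in ps⁻¹; the free-rotor rank-1
        orientational correlation time is 1/(2·d_rot).
    temperature:
        Kelvin; sets the rotational friction ζ_r = k_B·T/d_rot.
    dt:
        Integration step, ps.
    n_steps:
        Number of integration steps.
    seed:
        Seed for the ensemble's random stream; identical seed and
        configuration reproduce the orientation output bitwise.
    intrinsic_field:
        Optional static field per rotor, V/Å: shape (3,) applied to all
        rotors or (n_rotors, 3). Emulates the strong protein-generated
        field acting on first-shell waters.
    positions:
        Optional fixed rotor positions (n_rotors, 3) Å used by
        ``emit_trajectory``; defaults to a cubic lattice.
    sample_every:
        Store every k-th step (plus the initial state).
    """

    n_rotors: int
    mu: float = 2.3
    d_rot: float = 0.1
    temperature: float = 300.0
    dt: float = 0.05
    n_steps: int = 1000
    seed: int = 0
    intrinsic_field: Optional[np.ndarray] = None
    positions: Optional[np.ndarray] = None
    sample_every: int = 1

    def __post_init__(self):
        if self.n_rotors < 1:
            raise ValueError("n_rotors must be >= 1")
        if self.dt <= 0 or self.d_rot < 0 or self.mu < 0:
            raise ValueError("dt must be > 0, d_rot and mu non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.intrinsic_field is not None:
            f = np.asarray(self.intrinsic_field, dtype=float)
            if f.shape == (3,):
                f = np.broadcast_to(f, (self.n_rotors, 3)).copy()
            if f.shape != (self.n_rotors, 3):
                raise ValueError("intrinsic_field must have shape (3,) or (n,3)")
            self.intrinsic_field = f


@dataclass
class OrientationSeries:
    """Times (ps) and per-rotor unit orientation vectors (n_frames, n, 3)."""

    times: np.ndarray
    unit_vectors: np.ndarray

    def __post_init__(self):
        norms = np.linalg.norm(self.unit_vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientation vectors must be unit length")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_rotors(self) -> int:
        return self.unit_vectors.shape[1]

    def mean_x(self) -> np.ndarray:
        """Ensemble-mean x component per frame."""
        return self.unit_vectors[..., 0].mean(axis=1)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_ensemble(config: RotorEnsembleConfig, field: FieldSpec) -> OrientationSeries:
    """Integrate the overdamped rotational Langevin equation.

    Each rotor's unit dipole axis u evolves by an Euler–Maruyama step:
    deterministic angular drift (1/ζ_r)·μ u×E_total with ζ_r = k_B·T/D_r,
    i.e. du_drift = (μ D_r dt / k_B T)·(E − (u·E)u), plus isotropic
    rotational noise of variance 2·D_r·dt per tangent axis, with
    renormalization after every step. E_total is the applied field at time
    t plus any per-rotor intrinsic field.

    Raises if the deterministic rotation per step could exceed ~0.1 rad
    (μ·E_max·dt·D_r/k_BT > 0.1), which would invalidate the first-order
    scheme.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_rotors
    kbt = thermal_energy_ev(config.temperature)
    # drift prefactor: converts (V/Å) field into rad/ps angular drift
    coupling = config.mu * DEBYE_V_PER_ANGSTROM_TO_EV * config.d_rot / kbt

    e_applied_max = rms_to_max(field)
    e_static_max = 0.0
    if config.intrinsic_field is not None:
        e_static_max = float(np.linalg.norm(config.intrinsic_field, axis=1).max())
    max_step = coupling * (e_applied_max + e_static_max) * config.dt
    if max_step > 0.1:
        raise ValueError(
            f"dt too large: deterministic rotation per step is {max_step:.3f} rad "
            "(> 0.1); reduce dt or the field strength"
        )

    u = _random_unit_vectors(rng, n)
    sigma = math.sqrt(2.0 * config.d_rot * config.dt)

    n_saved = config.n_steps // config.sample_every + 1
    out = np.empty((n_saved, n, 3))
    times = np.empty(n_saved)
    out[0] = u
    times[0] = 0.0
    saved = 1

    t = 0.0
    for step in range(1, config.n_steps + 1):
        e_tot = np.broadcast_to(field_at(field, t), (n, 3))
        if config.intrinsic_field is not None:
            e_tot = e_tot + config.intrinsic_field
        # torque drift projected on the tangent plane: E - (u·E)u
        ue = np.einsum("ij,ij->i", u, e_tot)[:, None]
        drift = coupling * config.dt * (e_tot - ue * u)
        g = rng.standard_normal((n, 3)) * sigma
        noise = g - np.einsum("ij,ij->i", u, g)[:, None] * u
        u = u + drift + noise
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        t = step * config.dt
        if step % config.sample_every == 0:
            out[saved] = u
            times[saved] = t
            saved += 1
    return OrientationSeries(times=times, unit_vectors=out)


def langevin_alignment(x) -> np.ndarray:
    """Langevin function L(x) = coth(x) − 1/x, the equilibrium ⟨cos θ⟩.

    x = μE/(k_B·T) is the reduced field energy; the x→0 limit is handled by
    the series x/3 − x³/45 to avoid cancellation.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    if out.ndim == 0:
        return float(out)
    return out


def debye_lag(frequency: float, tau: float) -> float:
    """Debye-theory lag time arctan(ωτ)/ω in ps.

    frequency in GHz, tau in ps. The value lies in (0, period/4): it tends
    to τ for ωτ≪1 and saturates at a quarter period for ωτ≫1.
    """
    if frequency <= 0 or tau <= 0:
        raise ValueError("frequency and tau must be positive")
    omega = 2.0 * math.pi * frequency / 1000.0  # rad/ps
    return math.atan(omega * tau) / omega


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """A unit vector field perpendicular to each row of u."""
    helper = np.zeros_like(u)
    smallest = np.argmin(np.abs(u), axis=1)
    helper[np.arange(len(u)), smallest] = 1.0
    p = np.cross(u, helper)
    return p / np.linalg.norm(p, axis=1, keepdims=True)


def _lattice_positions(n: int, spacing: float) -> np.ndarray:
    side = math.ceil(n ** (1.0 / 3.0))
    grid = np.arange(side) * spacing
    xyz = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1)
    return xyz.reshape(-1, 3)[:n] + spacing / 2.0


def emit_trajectory(
    series: OrientationSeries, config: RotorEnsembleConfig, spacing: float = 20.0
) -> Tuple[Trajectory, Topology]:
    """Render rotors as 3-site neutral water-like molecules.

    Each rotor becomes an O(−2q) H(+q) H(+q) molecule of rigid TIP-like
    geometry whose molecular dipole has magnitude μ along the rotor axis;
    q is chosen so that Σq·r reproduces μ exactly. Analysing the result
    with ``collective_dipole_component`` therefore recovers μ·Σu_x.
    """
    n = series.n_rotors
    if config.positions is not None:
        centers = np.asarray(config.positions, dtype=float)
        if centers.shape != (n, 3):
            raise ValueError("positions must have shape (n_rotors, 3)")
    else:
        centers = _lattice_positions(n, spacing)
    extent = centers.max(initial=0.0) + spacing
    box = np.full(3, max(extent, spacing))

    mu_e_ang = config.mu / E_ANGSTROM_TO_DEBYE
    q = mu_e_ang / (2.0 * _OH_BOND * math.cos(_HALF_HOH))

    n_frames = series.n_frames
    positions = np.empty((n_frames, 3 * n, 3))
    for f in range(n_frames):
        u = series.unit_vectors[f]
        perp = _perpendicular(u)
        axial = _OH_BOND * math.cos(_HALF_HOH) * u
        lateral = _OH_BOND * math.sin(_HALF_HOH) * perp
        positions[f, 0::3] = centers
        positions[f, 1::3] = centers + axial + lateral
        positions[f, 2::3] = centers + axial - lateral

    charges = np.tile([-2.0 * q, q, q], n)
    masses = np.tile([15.999, 1.008, 1.008], n)
    mol_id = np.repeat(np.arange(n), 3)
    topo = Topology(
        charges=charges,
        masses=masses,
        mol_id=mol_id,
        mol_class=np.array(["water"] * n, dtype=object),
    )
    traj = Trajectory(
        times=series.times.copy(),
        positions=positions,
        box=np.tile(box, (n_frames, 1)),
    )
    return traj, topo


def uniform_water_box(
    n_waters: int,
    box_length: float,
    seed: int = 0,
    mu: float = 2.3,
    solute_center: bool = True,
    solute_charge: float = 0.0,
) -> Tuple[Trajectory, Topology]:
    """A single-frame box of randomly placed, randomly oriented waters.

    Emulates bulk solvent at number density n_waters/box_length³ around an
    optional one-site heavy "solute" placed at the box centre (distance
    reference for density profiles). Intended for tessellation/density
    fixtures, not for dynamics.
    """
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, box_length, size=(n_waters, 3))
    u = _random_unit_vectors(rng, n_waters)
    perp = _perpendicular(u)
    mu_e_ang = mu / E_ANGSTROM_TO_DEBYE
    q = mu_e_ang / (2.0 * _OH_BOND * math.cos(_HALF_HOH))
    axial = _OH_BOND * math.cos(_HALF_HOH) * u
    lateral = _OH_BOND * math.sin(_HALF_HOH) * perp

    pos = np.empty((3 * n_waters + (1 if solute_center else 0), 3))
    pos[0:3 * n_waters:3] = centers
    pos[1:3 * n_waters:3] = centers + axial + lateral
    pos[2:3 * n_waters:3] = centers + axial - lateral

    charges = np.tile([-2.0 * q, q, q], n_waters)
    masses = np.tile([15.999, 1.008, 1.008], n_waters)
    mol_id = np.repeat(np.arange(n_waters), 3)
    classes = ["water"] * n_waters
    if solute_center:
        pos[-1] = box_length / 2.0
        charges = np.append(charges, solute_charge)
        masses = np.append(masses, 12.011)
        mol_id = np.append(mol_id, n_waters)
        classes.append("protein")

    topo = Topology(
        charges=charges,
        masses=masses,
        mol_id=mol_id,
        mol_class=np.array(classes, dtype=object),
    )
    traj = Trajectory(
        times=np.array([0.0]),
        positions=pos[None, :, :],
        box=np.array([[box_length] * 3]),
    )
    return traj, topo
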