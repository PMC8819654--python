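"""Reading structures/trajectories and the native synthetic-trajectory dialect.

Standard coordinate formats (PDB/GRO and the trajectory formats MDAnalysis
understands) are read through MDAnalysis; since crystallographic formats
carry no partial charges, a charge table (CSV with columns
``resname,atom,charge[,mass]``) supplies per-site charges, and molecule
classes are resolved from residue names. Synthetic trajectories round-trip
bit-exactly through a single-container NumPy ``.npz`` dialect holding the
times/positions/box arrays and the topology tables under a versioned header.

Units everywhere: Å, ps, e, Debye.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .dipoles import Frame, Topology, Trajectory

__all__ = [
    "RunConfig",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "read_native_trajectory",
    "WATER_RESNAMES",
    "ION_RESNAMES",
]

logger = logging.getLogger(__name__)

NATIVE_VERSION = 1

WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "TIP4", "TIP5", "SPC", "SPCE", "T4P"}
ION_RESNAMES = {
    "NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-", "K+", "SOD", "CLA", "POT",
}

# fallback masses (g/mol) by element guess from the atom-name first letter
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "K": 39.098, "F": 18.998}


def _guess_mass(name: str) -> float:
    for ch in name:
        if ch.isalpha():
            return _MASSES.get(ch.upper(), 12.011)
    return 12.011


def _classify(resname: str) -> str:
    rn = resname.strip().upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    return "protein"


def read_structure(
    path, charge_table=None
) -> Tuple[Topology, Frame]:
    """Read a PDB/GRO-class structure into a Topology and reference Frame.

    ``charge_table`` is a CSV with columns ``resname,atom,charge`` and an
    optional ``mass`` column; it is required because crystallographic
    formats carry no partial charges. Residues named like water/ions
    become individual molecules; all remaining (protein) residues form one
    protein molecule.
    """
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe(str(path))
    atoms = u.atoms

    table = {}
    mass_table = {}
    if charge_table is not None:
        # keep_default_na: 'NA' is sodium, not a missing value
        df = pd.read_csv(charge_table, keep_default_na=False)
        for _, row in df.iterrows():
            key = (str(row["resname"]).strip().upper(), str(row["atom"]).strip().upper())
            table[key] = float(row["charge"])
            if "mass" in df.columns and not pd.isna(row.get("mass")):
                mass_table[key] = float(row["mass"])

    charges = np.empty(len(atoms))
    masses = np.empty(len(atoms))
    missing = []
    for i, a in enumerate(atoms):
        key = (a.resname.strip().upper(), a.name.strip().upper())
        if key in table:
            charges[i] = table[key]
        else:
            missing.append(f"{a.resname}:{a.name}")
            charges[i] = np.nan
        masses[i] = mass_table.get(key, _guess_mass(a.name))
    if missing:
        uniq = sorted(set(missing))
        raise ValueError(f"no charge entry for sites: {uniq}")

    # molecule assignment: each water/ion residue is one molecule; all
    # protein residues merge into a single protein molecule
    classes_per_res = [_classify(r.resname) for r in u.residues]
    mol_id = np.empty(len(atoms), dtype=int)
    mol_class: List[str] = []
    protein_mol = None
    for res, cls in zip(u.residues, classes_per_res):
        if cls == "protein":
            if protein_mol is None:
                protein_mol = len(mol_class)
                mol_class.append("protein")
            mid = protein_mol
        else:
            mid = len(mol_class)
            mol_class.append(cls)
        mol_id[res.atoms.ix] = mid

    topo = Topology(
        charges=charges,
        masses=masses,
        mol_id=mol_id,
        mol_class=np.array(mol_class, dtype=object),
    )
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ValueError("structure carries no box dimensions")
    frame = Frame(time=0.0, positions=atoms.positions.astype(float), box=dims[:3].astype(float))
    return topo, frame


def write_trajectory(path, trajectory: Trajectory, topology: Topology) -> None:
    """Write the native ``.npz`` synthetic-trajectory container (lossless)."""
    np.savez(
        path,
        version=np.array([NATIVE_VERSION]),
        times=trajectory.times,
        positions=trajectory.positions,
        box=trajectory.box,
        charges=topology.charges,
        masses=topology.masses,
        mol_id=topology.mol_id,
        mol_class=np.array([str(c) for c in topology.mol_class]),
    )


def read_native_trajectory(path) -> Tuple[Trajectory, Topology]:
    """Read the native ``.npz`` dialect back; bitwise round trip."""
    try:
        data = np.load(path, allow_pickle=False)
    except Exception as exc:  # zipfile/format errors on truncation
        raise IOError(f"cannot read native trajectory {path}: {exc}") from exc
    required = {"version", "times", "positions", "box", "charges", "masses",
                "mol_id", "mol_class"}
    missing = required - set(data.files)
    if missing:
        raise IOError(f"native trajectory missing arrays: {sorted(missing)}")
    if int(data["version"][0]) != NATIVE_VERSION:
        raise IOError(f"unsupported native trajectory version {data['version'][0]}")
    topo = Topology(
        charges=data["charges"],
        masses=data["masses"],
        mol_id=data["mol_id"],
        mol_class=data["mol_class"].astype(object),
    )
    traj = Trajectory(times=data["times"], positions=data["positions"], box=data["box"])
    if traj.n_sites != topo.n_sites:
        raise ValueError(
            f"site count mismatch: trajectory {traj.n_sites} vs topology {topo.n_sites}"
        )
    return traj, topo


def read_trajectory(path, topology: Topology, structure=None) -> Trajectory:
    """Read a trajectory and validate it against a topology.

    ``.npz`` files use the native dialect; any other extension is handed
    to MDAnalysis (which then needs ``structure`` for topology-bearing
    formats). Uniform 'sampled every Δt' time spacing is enforced; a
    non-uniform or non-increasing time axis reports the offending frame.
    """
    path = Path(path)
    if path.suffix == ".npz":
        traj, topo = read_native_trajectory(path)
        if topo.n_sites != topology.n_sites:
            raise ValueError(
                f"site count mismatch: file {topo.n_sites} vs topology {topology.n_sites}"
            )
        return traj
    import MDAnalysis as mda

    u = mda.Universe(str(structure) if structure else str(path), str(path))
    if len(u.atoms) != topology.n_sites:
        raise ValueError(
            f"site count mismatch: file {len(u.atoms)} vs topology {topology.n_sites}"
        )
    times, positions, boxes = [], [], []
    for ts in u.trajectory:
        times.append(float(ts.time))
        positions.append(u.atoms.positions.astype(float).copy())
        boxes.append(ts.dimensions[:3].astype(float).copy())
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(positions),
        box=np.asarray(boxes),
    )


@dataclass
class RunConfig:
    """Declarative analysis run configuration (YAML-backed).

    The field block mirrors FieldSpec (waveform, e_rms_V_per_A,
    frequency_GHz, direction, phase_origin_ps); shell boundaries, window
    spec, analysis groups, output directory and the global seed complete
    the run description.
    """

    structure: Optional[str] = None
    trajectory: Optional[str] = None
    charge_table: Optional[str] = None
    field: dict = dc_field(default_factory=dict)
    shell_boundaries: Tuple[float, float] = (2.25, 6.0)
    window: dict = dc_field(default_factory=dict)
    groups: Tuple[str, ...] = ("protein", "shell1", "shell2", "bulk")
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for key in ("structure", "trajectory", "charge_table"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")
        return cfg

    def field_spec(self):
        from .field import FieldSpec

        f = self.field
        return FieldSpec(
            waveform=f.get("waveform", "static"),
            e_rms=f.get("e_rms_V_per_A", 0.0),
            frequency=f.get("frequency_GHz", 0.0),
            direction=tuple(f.get("direction", (1.0, 0.0, 0.0))),
            phase_origin=f.get("phase_origin_ps", 0.0),
        )

    def provenance(self) -> dict:
        """Config hash and input checksums, logged by every stage."""
        blob = yaml.safe_dump(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        out = {"config_sha256": hashlib.sha256(blob).hexdigest()}
        for key in ("structure", "trajectory", "charge_table"):
            p = getattr(self, key)
            if p is not None and Path(p).exists():
                out[f"{key}_sha256"] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        logger.info("provenance: %s", out)
        return out


# -- tabular outputs (units in headers) -------------------------------------

def write_series_csv(series, path) -> None:
    """DipoleSeries as CSV: time_ps, dipole_x_D."""
    pd.DataFrame({"time_ps": series.times, "dipole_x_D": series.dipole_x}).to_csv(
        path, index=False
    )


def write_acf_csv(result, path) -> None:
    """ACFResult as CSV: lag_ps, acf."""
    pd.DataFrame({"lag_ps": result.lags, "acf": result.acf}).to_csv(path, index=False)


def write_lag_csv(results, path) -> None:
    """Lag fits as CSV: group, window_id, t_lag_ps, amplitude_D, offset_D, residual_D."""
    pd.DataFrame(
        [
            {
                "group": r.group,
                "window_id": r.window_id,
                "t_lag_ps": r.t_lag,
                "amplitude_D": r.amplitude,
                "offset_D": r.offset,
                "residual_D": r.residual,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_windows_csv(windows, stabilities, path) -> None:
    """Window table CSV: window_id, start_ps, end_ps, stability_fraction, retained."""
    rows = []
    for i, ((start, end), st) in enumerate(zip(windows, stabilities)):
        rows.append(
            {
                "window_id": i,
                "start_ps": start,
                "end_ps": end,
                "stability_fraction": None if st is None else st.fraction,
                "retained": None if st is None else st.retained,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
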