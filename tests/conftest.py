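"""Shared builders for small synthetic systems used across the test suite."""

import numpy as np
import pytest

from hydrodipole.dipoles import Frame, Topology, Trajectory
from hydrodipole._units import E_ANGSTROM_TO_DEBYE


def two_site_dipole_topology(n_waters, dipole_d=2.0, extra_protein_sites=0):
    """Waters modelled as ±q site pairs 1 Å apart (dipole known exactly).

    Optionally prepends a protein molecule of ``extra_protein_sites`` carbon
    sites with zero charge.
    """
    q = dipole_d / E_ANGSTROM_TO_DEBYE
    charges, masses, mol_id, classes = [], [], [], []
    for _ in range(extra_protein_sites):
        charges.append(0.0)
        masses.append(12.011)
        mol_id.append(0)
    if extra_protein_sites:
        classes.append("protein")
    for w in range(n_waters):
        charges += [q, -q]
        masses += [15.999, 2.016]
        mol_id += [len(classes), len(classes)]
        classes.append("water")
    return Topology(
        charges=np.array(charges),
        masses=np.array(masses),
        mol_id=np.array(mol_id),
        mol_class=np.array(classes, dtype=object),
    )


def frame_from_positions(positions, box=100.0, time=0.0):
    return Frame(time=time, positions=np.asarray(positions, float),
                 box=np.full(3, float(box)))


@pytest.fixture
def water_pair_frame():
    """Two ±q 'waters' with x-dipoles 2 D and 1 D, plus their topology."""
    topo = two_site_dipole_topology(2, dipole_d=2.0)
    # second water's +/- separation halved -> dipole 1 D
    pos = np.array(
        [[1.0, 0.0, 0.0], [0.0, 0.0, 0.0],
         [10.5, 5.0, 5.0], [10.0, 5.0, 5.0]]
    )
    return frame_from_positions(pos), topo
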