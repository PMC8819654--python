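"""Physical constants and unit conversions used throughout the package.

Conventions: coordinates in Å, times in ps, charges in e, dipoles in D,
electric fields in V/Å, energies in eV, frequencies in GHz.
"""

# 1 e·Å in Debye: e * 1 Å / (1 D) = 1.602176634e-29 C·m / 3.33564e-30 C·m
E_ANGSTROM_TO_DEBYE = 4.80321

# Boltzmann constant in eV/K
KB_EV_PER_K = 8.617333262e-5

# 1 D · (V/Å) in eV: 3.33564e-30 C·m * 1e10 V/m / 1.602176634e-19 J/eV
DEBYE_V_PER_ANGSTROM_TO_EV = 0.2081943

# Coulomb constant k_C = 1/(4 pi eps0) * e / Å², expressed in (V/Å) per (e/Å²)
COULOMB_V_ANGSTROM_PER_E = 14.3996

# Molar mass of water, g/mol
WATER_MOLAR_MASS = 18.0153

AVOGADRO = 6.02214076e23

# GHz * ps: one period in ps is 1000 / frequency_GHz
PS_PER_GHZ_PERIOD = 1000.0


def thermal_energy_ev(temperature_k: float) -> float:
    """k_B·T in eV (0.025852 eV at 300 K)."""
    return KB_EV_PER_K * temperature_k
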