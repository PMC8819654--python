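"""Protein formal charge at neutral pH from sequence.

At pH 7 the standard assignment gives Arg and Lys +1, Asp and Glu −1,
His neutral, and the free termini +1/−1 (net zero for an unmodified
chain). Hen egg-white lysozyme's 129-residue mature chain comes out at
+8 e, which is why its solvated simulation box carries 8 chloride
counterions.
"""

from __future__ import annotations

__all__ = ["HEWL_SEQUENCE", "formal_charge_at_ph7"]

# Mature hen egg-white lysozyme chain (129 residues, UniProt P00698 without
# the signal peptide; the chain of the triclinic crystal structure).
HEWL_SEQUENCE = (
    "KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAKFESNFNTQATNRNTDGSTDYGILQINSRWWCNDGRTP"
    "GSRNLCNIPCSALLSSDITASVNCAKKIVSDGNGMNAWVAWRNRCKGTDVQAWIRGCRL"
)

_CHARGES = {"R": 1, "K": 1, "D": -1, "E": -1, "H": 0}

_AMINO = set("ACDEFGHIKLMNPQRSTVWY")


def formal_charge_at_ph7(sequence: str, include_termini: bool = True) -> int:
    """Net formal charge (e) of a protein chain at pH 7.

    Counts +1 per Arg/Lys, −1 per Asp/Glu, 0 for His; the N/C termini
    contribute +1 and −1 (net 0) when ``include_termini``.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - _AMINO
    if bad:
        raise ValueError(f"unknown residue codes: {sorted(bad)}")
    charge = sum(_CHARGES.get(aa, 0) for aa in seq)
    if include_termini:
        charge += 1 - 1
    return charge
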