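"""Amino-acid and physical constants shared across the package."""

from __future__ import annotations

import numpy as np

#: Simulation temperature, K.  Energies throughout are in units of kBT at
#: this temperature (kBT = 2.494 kJ/mol at 300 K).
TEMPERATURE_K = 300.0
BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
KT_JOULE = BOLTZMANN_J_PER_K * TEMPERATURE_K

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_AA3 = sorted(THREE_TO_ONE)
CANONICAL_AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: Non-canonical residue names mapped to a canonical stand-in on read.
#: Selenomethionine is the common crystallographic substitution.
RESIDUE_ALIASES = {"MSE": "MET"}


def canonical_three(code: str) -> str:
    code = code.strip().upper()
    code = RESIDUE_ALIASES.get(code, code)
    if code not in THREE_TO_ONE:
        raise ValueError(f"non-canonical residue code {code!r}")
    return code


#: Mean amino-acid residue volumes (A^3), Zamyatnin (1972).
RESIDUE_VOLUMES_A3 = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

#: Bead radii (nm): radius of the sphere with the residue's mean volume.
BEAD_RADII_NM = {
    aa: float((3.0 * v * 1e-3 / (4.0 * np.pi)) ** (1.0 / 3.0))
    for aa, v in RESIDUE_VOLUMES_A3.items()
}

#: Dayhoff background amino-acid frequencies (fractions summing to ~1),
#: used to average per-residue Hamaker constants into a material constant.
DAYHOFF_FREQUENCIES = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}

#: Side-chain / terminal pKa values (EMBOSS defaults) for the pH-7 charge.
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
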