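"""Shared fixtures: synthetic PDB text builders, materials, proteins."""

from __future__ import annotations

import numpy as np
import pytest

from npadsorb import NPSphere, generate_synthetic_protein
from npadsorb.structure import native_confinement_radius
from npadsorb.fixtures import gold_like_spec, make_material, titania_like_spec


def make_pdb_text(
    residues,
    seqres: str | None = None,
    chain: str = "A",
    altloc_spec: dict[int, list[tuple[str, float]]] | None = None,
) -> str:
    """Build minimal PDB text with CA-only ATOM records.

    ``residues``: list of (resname3, resseq, (x, y, z) in angstroms,
    occupancy).  ``altloc_spec`` maps resseq -> [(altloc_char, occupancy)]
    to emit alternate-location copies of that residue's CA (coordinates
    offset by 0.5 A per conformer so they are distinguishable).
    """
    lines = []
    if seqres:
        three = {
            "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
            "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
            "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
            "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
        }
        codes = [three[c] for c in seqres]
        for start in range(0, len(codes), 13):
            chunk = codes[start:start + 13]
            lines.append(
                f"SEQRES {start // 13 + 1:3d} {chain} {len(codes):4d}  "
                + " ".join(chunk)
            )
    serial = 1
    altloc_spec = altloc_spec or {}
    for resname, resseq, (x, y, z), occ in residues:
        variants = altloc_spec.get(resseq, [(" ", occ)])
        for k, (alt, vocc) in enumerate(variants):
            dx = 0.5 * k
            lines.append(
                f"ATOM  {serial:5d}  CA {alt}{resname} {chain}{resseq:4d}    "
                f"{x + dx:8.3f}{y:8.3f}{z:8.3f}{vocc:6.2f}  0.00           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def simple_residues(seq3: list[str], start: int = 1, spacing: float = 3.8):
    """Residue tuples along x at CA-CA spacing (angstroms), occupancy 1."""
    return [
        (code, start + i, (spacing * i, 0.0, 0.0), 1.0)
        for i, code in enumerate(seq3)
    ]


@pytest.fixture(scope="session")
def gold_material():
    return make_material(gold_like_spec(), seed=11)


@pytest.fixture(scope="session")
def titania_material():
    return make_material(titania_like_spec(), seed=11)


@pytest.fixture(scope="session")
def small_protein():
    """Compact 40-residue globule at native-like packing density."""
    return generate_synthetic_protein(
        40, seed=7, confinement_radius=native_confinement_radius(40)
    )


@pytest.fixture(scope="session")
def small_np(gold_material):
    return NPSphere(gold_material, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
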