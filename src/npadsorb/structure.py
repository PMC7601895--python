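"""Coarse-grained protein structures at one bead per residue.

A protein is represented as an ordered chain of beads, one per resolved
residue, each centred on the residue's alpha-carbon and carrying the
occupancy reported in the source PDB file.  Coordinates are stored in
nanometres; RMSDs are reported in angstroms, following the convention of
most structural-comparison plots.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices  # noqa: F401 (aligner only)
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

from .constants import (
    BEAD_RADII_NM,
    ONE_TO_THREE,
    THREE_TO_ONE,
    canonical_three,
)

__all__ = [
    "Bead",
    "CGProtein",
    "AlignmentMask",
    "load_pdb_to_cg",
    "load_fasta_sequence",
    "mask_to_reference",
    "rmsd",
    "perturb_structure",
    "generate_synthetic_protein",
    "native_confinement_radius",
]

#: CA-CA virtual bond length of an extended polypeptide, nm.
CA_CA_STEP_NM = 0.38
#: Minimum allowed bead-bead distance in synthetic chains, nm.
MIN_BEAD_SEPARATION_NM = 0.36


@dataclass
class Bead:
    """One amino acid: a sphere centred at the residue's alpha carbon."""

    residue_code: str          # canonical 3-letter code
    position: np.ndarray       # (3,) nm
    occupancy: float = 1.0
    bead_radius: float | None = None  # nm; default looked up per residue

    def __post_init__(self):
        self.residue_code = canonical_three(self.residue_code)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("bead position must be a 3-vector")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        if self.bead_radius is None:
            self.bead_radius = BEAD_RADII_NM[self.residue_code]
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")


@dataclass
class CGProtein:
    """Ordered bead chain plus the full sequence and a located/missing mask.

    ``sequence`` covers every residue the protein has (e.g. from SEQRES),
    while ``beads`` holds only those whose coordinates are known;
    ``present_mask[i]`` says whether sequence position ``i`` (0-based) has a
    bead.  ``residue_numbers`` retains the author numbering for reporting.
    """

    id: str
    sequence: str
    beads: list[Bead]
    residue_numbers: list[int] = field(default_factory=list)
    present_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.present_mask is None:
            self.present_mask = np.ones(len(self.sequence), dtype=bool)
        self.present_mask = np.asarray(self.present_mask, dtype=bool)
        if len(self.present_mask) != len(self.sequence):
            raise ValueError("present_mask length must equal sequence length")
        if int(self.present_mask.sum()) != len(self.beads):
            raise ValueError(
                f"{int(self.present_mask.sum())} located positions but "
                f"{len(self.beads)} beads"
            )
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, len(self.beads) + 1))
        if len(self.residue_numbers) != len(self.beads):
            raise ValueError("need one residue number per bead")
        # cross-check bead residue codes against the sequence
        seq_pos = np.flatnonzero(self.present_mask)
        for pos, bead in zip(seq_pos, self.beads):
            expected = ONE_TO_THREE.get(self.sequence[pos])
            if expected is not None and expected != bead.residue_code:
                raise ValueError(
                    f"bead at sequence position {pos} is {bead.residue_code}, "
                    f"sequence says {expected}"
                )

    # -- array views -------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """Bead positions, shape (n_beads, 3), nm."""
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([b.occupancy for b in self.beads], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.bead_radius for b in self.beads], dtype=float)

    @property
    def residue_codes(self) -> list[str]:
        return [b.residue_code for b in self.beads]

    @property
    def located_sequence(self) -> str:
        """One-letter sequence of the located residues only."""
        return "".join(THREE_TO_ONE[b.residue_code] for b in self.beads)

    @property
    def centre_of_mass(self) -> np.ndarray:
        """Unweighted centroid of the bead positions, nm."""
        return self.coords.mean(axis=0)

    def __len__(self) -> int:
        return len(self.beads)

    def with_coords(self, coords: np.ndarray, suffix: str = "") -> "CGProtein":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.beads), 3):
            raise ValueError("coordinate array shape mismatch")
        beads = [replace(b, position=c.copy()) for b, c in zip(self.beads, coords)]
        return CGProtein(
            id=self.id + suffix,
            sequence=self.sequence,
            beads=beads,
            residue_numbers=list(self.residue_numbers),
            present_mask=self.present_mask.copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write beads as TSV: index, residue, x, y, z (nm), occupancy."""
        df = pd.DataFrame(
            {
                "index": self.residue_numbers,
                "residue": self.residue_codes,
                "x_nm": self.coords[:, 0],
                "y_nm": self.coords[:, 1],
                "z_nm": self.coords[:, 2],
                "occupancy": self.occupancies,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, protein_id: str | None = None) -> "CGProtein":
        df = pd.read_csv(path, sep="\t")
        beads = [
            Bead(
                residue_code=row.residue,
                position=np.array([row.x_nm, row.y_nm, row.z_nm]),
                occupancy=row.occupancy,
            )
            for row in df.itertuples()
        ]
        seq = "".join(THREE_TO_ONE[b.residue_code] for b in beads)
        return cls(
            id=protein_id or str(path),
            sequence=seq,
            beads=beads,
            residue_numbers=[int(i) for i in df["index"]],
        )

    def to_pdb(self, path) -> None:
        """Write a minimal CA-only PDB (angstroms) for visualisation."""
        lines = []
        for i, bead in enumerate(self.beads):
            x, y, z = bead.position * 10.0  # nm -> A
            lines.append(
                f"ATOM  {i + 1:5d}  CA  {bead.residue_code} A"
                f"{self.residue_numbers[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{bead.occupancy:6.2f}  0.00           C"
            )
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class AlignmentMask:
    """Record of which model sequence positions survived masking."""

    reference_id: str
    model_id: str
    kept_positions: list[int]  # 0-based model sequence positions, increasing

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.kept_positions, self.kept_positions[1:])):
            raise ValueError("kept positions must be strictly increasing")


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _seqres_sequences(pdb_text: str) -> dict[str, str]:
    """Chain id -> one-letter SEQRES sequence (empty dict if no SEQRES)."""
    out = {}
    try:
        for rec in SeqIO.parse(io.StringIO(pdb_text), "pdb-seqres"):
            chain = rec.annotations.get("chain", rec.id.split(":")[-1])
            out[chain] = str(rec.seq)
    except Exception:  # no SEQRES records at all
        return {}
    return out


def load_pdb_to_cg(
    pdb_text: str,
    chain_selector: str | None = None,
    protein_id: str = "protein",
) -> CGProtein:
    """Coarse-grain PDB text into one bead per located residue.

    Each residue with an alpha carbon becomes a bead at the CA position
    (converted to nm) carrying the CA occupancy.  For alternate locations
    the highest-occupancy conformer is kept, with its own occupancy.
    Selenomethionine is read as methionine.  If SEQRES records are present
    the full sequence is taken from them and located residues are mapped
    onto it by alignment, so unresolved residues show up as gaps in
    ``present_mask``.

    Raises ``ValueError`` if no CA atoms are found, or if the file has
    several chains and no ``chain_selector`` was given.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id, io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("no ATOM records with CA atoms found in PDB text")
    chains = list(model.get_chains())
    if chain_selector is not None:
        chains = [c for c in chains if c.id == chain_selector]
        if not chains:
            raise ValueError(f"chain {chain_selector!r} not found")
    if len(chains) > 1:
        raise ValueError(
            f"structure has chains {[c.id for c in chains]}; pass chain_selector"
        )
    if not chains:
        raise ValueError("no chains found in PDB text")
    chain = chains[0]

    beads, numbers = [], []
    for residue in chain.get_residues():
        hetflag = residue.id[0]
        if hetflag not in (" ", "H_MSE"):
            continue
        if "CA" not in residue:
            continue
        ca = residue["CA"]
        if ca.is_disordered():
            # DisorderedAtom: pick the alternate location with the highest
            # occupancy and keep that occupancy as the bead weight.
            ca = max(ca.child_dict.values(), key=lambda a: a.get_occupancy() or 0.0)
        code = canonical_three(residue.get_resname())
        occ = ca.get_occupancy()
        occ = 1.0 if occ is None or occ <= 0 else min(float(occ), 1.0)
        beads.append(
            Bead(residue_code=code, position=np.asarray(ca.get_coord()) / 10.0,
                 occupancy=occ)
        )
        numbers.append(residue.id[1])
    if not beads:
        raise ValueError("no CA atoms found in PDB text")

    located = "".join(THREE_TO_ONE[b.residue_code] for b in beads)
    seqres = _seqres_sequences(pdb_text).get(chain.id, "")
    if seqres and len(seqres) >= len(located):
        mask = _map_onto_reference(seqres, located)
        if mask is None:  # alignment failed; fall back to located-only
            sequence, mask = located, np.ones(len(located), dtype=bool)
        else:
            sequence = seqres
    else:
        sequence, mask = located, np.ones(len(located), dtype=bool)

    return CGProtein(
        id=protein_id,
        sequence=sequence,
        beads=beads,
        residue_numbers=numbers,
        present_mask=mask,
    )


def load_fasta_sequence(fasta_text: str) -> tuple[str, str]:
    """Return (record id, sequence) of the first FASTA record."""
    rec = next(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    return rec.id, str(rec.seq)


# ---------------------------------------------------------------------------
# Alignment and masking
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _aligned_position_map(seq_a: str, seq_b: str) -> dict[int, int]:
    """Map 0-based positions of seq_b onto seq_a via global alignment."""
    aln = _make_aligner().align(seq_a, seq_b)[0]  # leftmost optimal alignment
    mapping = {}
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            mapping[b0 + off] = a0 + off
    return mapping


def _map_onto_reference(full_seq: str, located_seq: str) -> np.ndarray | None:
    """Boolean mask over full_seq marking positions matched by located_seq."""
    mapping = _aligned_position_map(full_seq, located_seq)
    if len(mapping) != len(located_seq):
        return None
    mask = np.zeros(len(full_seq), dtype=bool)
    mask[sorted(mapping.values())] = True
    return mask


def mask_to_reference(
    reference: CGProtein,
    model: CGProtein,
    min_identity: float = 0.5,
) -> tuple[CGProtein, AlignmentMask]:
    """Hide model residues that are unresolved in the reference structure.

    Predicted structures place every residue, experimental ones may not;
    masking produces a model with exactly the residues the reference has
    located, so the two can be compared bead by bead.  Model positions are
    mapped onto the reference by global sequence alignment; a model bead is
    kept only when its aligned reference position exists and is located.

    Refuses (with a warning) when alignment identity falls below
    ``min_identity``, which usually means the two proteins were paired by
    mistake.
    """
    mapping = _aligned_position_map(reference.sequence, model.sequence)
    matches = sum(
        1 for mpos, rpos in mapping.items()
        if model.sequence[mpos] == reference.sequence[rpos]
    )
    identity = matches / max(len(reference.sequence), len(model.sequence))
    if identity < min_identity:
        msg = (
            f"alignment identity {identity:.2f} below floor {min_identity:.2f}; "
            f"refusing to mask {model.id} against {reference.id}"
        )
        warnings.warn(msg)
        raise ValueError(msg)

    model_positions = np.flatnonzero(model.present_mask)
    keep_seq_positions = []
    for pos in model_positions:
        rpos = mapping.get(int(pos))
        if rpos is not None and reference.present_mask[rpos]:
            keep_seq_positions.append(int(pos))

    keep_set = set(keep_seq_positions)
    new_beads, new_numbers = [], []
    for pos, bead, num in zip(model_positions, model.beads, model.residue_numbers):
        if int(pos) in keep_set:
            new_beads.append(bead)
            new_numbers.append(num)
    new_mask = np.zeros(len(model.sequence), dtype=bool)
    new_mask[keep_seq_positions] = True

    masked = CGProtein(
        id=model.id + "|masked",
        sequence=model.sequence,
        beads=new_beads,
        residue_numbers=new_numbers,
        present_mask=new_mask,
    )
    return masked, AlignmentMask(
        reference_id=reference.id,
        model_id=model.id,
        kept_positions=keep_seq_positions,
    )


# ---------------------------------------------------------------------------
# Comparison and perturbation
# ---------------------------------------------------------------------------

def rmsd(a: CGProtein, b: CGProtein, superpose: bool = False) -> float:
    """CA-CA root-mean-square deviation in angstroms.

    With ``superpose`` the optimal rigid-body least-squares superposition
    (Kabsch) is applied first.  Bead counts must match; mask first if not.
    """
    if len(a) != len(b):
        raise ValueError(
            f"bead counts differ ({len(a)} vs {len(b)}); "
            "apply mask_to_reference first"
        )
    xa = a.coords * 10.0  # nm -> A
    xb = b.coords * 10.0
    if superpose:
        sup = SVDSuperimposer()
        sup.set(xa, xb)
        sup.run()
        return float(sup.get_rms())
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def perturb_structure(p: CGProtein, target_rmsd: float, seed: int) -> CGProtein:
    """Displace every bead by isotropic Gaussian noise of a chosen size.

    Per-axis sigma is ``target_rmsd/sqrt(3)`` (angstroms), so the expected
    squared displacement per bead is ``target_rmsd**2`` and the achieved
    RMSD concentrates on the target for long chains.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    if target_rmsd == 0:
        return p.with_coords(p.coords, suffix="|perturbed0")
    rng = np.random.default_rng(seed)
    sigma_nm = (target_rmsd / np.sqrt(3.0)) / 10.0
    noise = rng.normal(scale=sigma_nm, size=(len(p), 3))
    return p.with_coords(p.coords + noise, suffix=f"|rmsd{target_rmsd:g}")


# ---------------------------------------------------------------------------
# Synthetic chains
# ---------------------------------------------------------------------------

def native_confinement_radius(n_residues: int) -> float:
    """Confinement radius (nm) giving a synthetic chain roughly the packing
    density of a folded globule (~0.13 nm^3 per residue)."""
    return 0.42 * n_residues ** (1.0 / 3.0)


def generate_synthetic_protein(
    n_residues: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    confinement_radius: float | None = None,
    max_restarts: int = 50,
) -> CGProtein:
    """Self-avoiding random-walk chain with realistic CA-CA geometry.

    Consecutive beads are 0.38 nm apart and no two beads come closer than
    0.36 nm.  Residue types are drawn from ``composition`` (one-letter code
    -> frequency; default natural abundances).  ``confinement_radius``
    (nm, about the origin) biases the walk into a globule, handy for
    fixtures that need buried residues.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    from .constants import DAYHOFF_FREQUENCIES

    comp = composition or DAYHOFF_FREQUENCIES
    letters = sorted(comp)
    probs = np.array([comp[aa] for aa in letters], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("composition frequencies must be non-negative, sum > 0")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(letters, size=n_residues, p=probs))

    for _ in range(max_restarts):
        coords = _self_avoiding_walk(n_residues, rng, confinement_radius)
        if coords is not None:
            break
    else:
        raise RuntimeError(
            f"failed to place a {n_residues}-residue chain after "
            f"{max_restarts} restarts"
        )

    beads = [
        Bead(residue_code=ONE_TO_THREE[aa], position=c)
        for aa, c in zip(seq, coords)
    ]
    return CGProtein(id=f"synthetic-{n_residues}-{seed}", sequence=seq, beads=beads)


def _self_avoiding_walk(
    n: int, rng: np.random.Generator, confinement: float | None
) -> np.ndarray | None:
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = coords[i - 1] + CA_CA_STEP_NM * u
            if confinement is not None and np.linalg.norm(cand) > confinement:
                continue
            d2 = np.sum((coords[:i] - cand) ** 2, axis=1)
            if d2.min() >= MIN_BEAD_SEPARATION_NM**2:
                coords[i] = cand
                break
        else:
            return None
    return coords - coords.mean(axis=0)
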