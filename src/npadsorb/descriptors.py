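"""Sequence- and structure-derived protein predictors.

Sequence descriptors follow the EMBOSS pepstats conventions: molecular
weight, residue counts and molar fractions, class molar fractions (tiny,
small, aliphatic, aromatic, non-polar, polar, charged, basic, acidic) and
the net charge at pH 7 from a Henderson-Hasselbalch model.  Structure
descriptors are computed on the coarse-grained bead model: surface area,
volume and sphericity of the union of bead spheres, plus counts of surface
residues per type and per class from a rolling-probe accessibility test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from skimage import measure

from .constants import CANONICAL_AA1, ONE_TO_THREE, PKA, THREE_TO_ONE
from .structure import CGProtein

__all__ = [
    "AAClassScheme",
    "EMBOSS_CLASSES",
    "sequence_descriptors",
    "surface_residues",
    "structure_descriptors",
    "all_descriptors",
]

#: Default rolling-probe radius (water), nm.
DEFAULT_PROBE_NM = 0.14
#: Default voxel pitch for the volume/area estimate, nm.
DEFAULT_VOXEL_NM = 0.1

EMBOSS_CLASSES: dict[str, frozenset] = {
    "Tiny": frozenset("ACGST"),
    "Small": frozenset("ACDGNPSTV"),
    "Aliphatic": frozenset("ILV"),
    "Aromatic": frozenset("FHWY"),
    "NonPolar": frozenset("ACFGILMPVWY"),
    "Polar": frozenset("DEHKNQRST"),
    "Charged": frozenset("DEHKR"),
    "Basic": frozenset("HKR"),
    "Acidic": frozenset("DE"),
}


@dataclass
class AAClassScheme:
    """Named amino-acid classes; defaults to the EMBOSS pepstats groups."""

    classes: dict[str, frozenset] = field(
        default_factory=lambda: dict(EMBOSS_CLASSES)
    )

    def __post_init__(self):
        covered = set().union(*self.classes.values())
        if not set(CANONICAL_AA1) <= covered:
            raise ValueError(
                f"residues not covered by any class: "
                f"{sorted(set(CANONICAL_AA1) - covered)}"
            )


def net_charge_at_pH(seq: str, pH: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge with EMBOSS pKa values."""
    pos = 1.0 / (1.0 + 10.0 ** (pH - PKA["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (PKA["Cterm"] - pH))
    for aa in seq:
        if aa in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10.0 ** (pH - PKA[aa]))
        elif aa in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10.0 ** (PKA[aa] - pH))
    return pos - neg


def sequence_descriptors(
    seq: str, scheme: AAClassScheme | None = None
) -> pd.Series:
    """Sequence-derived predictors as a named Series.

    Molecular weight is the average-isotope peptide mass (residue masses
    minus one water per peptide bond).  Raises on non-canonical letters.
    """
    scheme = scheme or AAClassScheme()
    seq = seq.upper()
    bad = set(seq) - set(CANONICAL_AA1)
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
    n = len(seq)
    out: dict[str, float] = {
        "Molecular Weight": float(molecular_weight(seq, seq_type="protein")),
        "Length": float(n),
        "Net Charge pH7": net_charge_at_pH(seq),
    }
    for aa in CANONICAL_AA1:
        count = seq.count(aa)
        out[f"{ONE_TO_THREE[aa]} Number"] = float(count)
        out[f"Molar Fraction {ONE_TO_THREE[aa]}"] = count / n
    for name, members in scheme.classes.items():
        out[f"Molar Fraction {name}"] = sum(seq.count(aa) for aa in members) / n
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Surface detection and geometry on the bead model
# ---------------------------------------------------------------------------

def _sphere_points(n: int = 128) -> np.ndarray:
    """Quasi-uniform unit-sphere directions (golden-spiral lattice)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    return np.stack([rho * np.cos(golden * i), rho * np.sin(golden * i), z], axis=1)


def surface_residues(
    p: CGProtein, probe_radius: float = DEFAULT_PROBE_NM, n_points: int = 128
) -> np.ndarray:
    """Boolean flag per bead: does it retain solvent-accessible area?

    Shrake-Rupley on the bead model: test points on each bead's
    probe-expanded sphere are checked against every other expanded sphere;
    a bead with at least one free point is a surface bead.
    """
    if len(p) == 0:
        raise ValueError("protein has no beads")
    coords = p.coords
    radii = p.radii + probe_radius
    dirs = _sphere_points(n_points)
    flags = np.zeros(len(p), dtype=bool)
    for i in range(len(p)):
        pts = coords[i] + radii[i] * dirs
        free = np.ones(n_points, dtype=bool)
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        neighbours = np.flatnonzero(
            (d2 < (radii + radii[i]) ** 2) & (np.arange(len(p)) != i)
        )
        for j in neighbours:
            free &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
            if not free.any():
                break
        flags[i] = free.any()
    return flags


def _signed_distance_grid(
    coords: np.ndarray, radii: np.ndarray, voxel: float
) -> tuple[np.ndarray, float]:
    """Signed distance to the union-of-spheres surface on a padded grid."""
    pad = radii.max() + 3 * voxel
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    grid = np.full(shape, np.inf, dtype=float)
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    for c, r in zip(coords, radii):
        # local window around this bead
        i0 = np.maximum(((c - r - 2 * voxel) - lo) // voxel, 0).astype(int)
        i1 = np.minimum(((c + r + 2 * voxel) - lo) // voxel + 2, shape).astype(int)
        xs = axes[0][i0[0]:i1[0]] - c[0]
        ys = axes[1][i0[1]:i1[1]] - c[1]
        zs = axes[2][i0[2]:i1[2]] - c[2]
        d = np.sqrt(
            xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
        ) - r
        window = grid[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(window, d, out=window)
    return grid, voxel


def _mesh_area_volume(coords: np.ndarray, radii: np.ndarray, voxel: float):
    import trimesh

    grid, spacing = _signed_distance_grid(coords, radii, voxel)
    # outside voxels still at +inf do not border the surface; cap them
    np.clip(grid, -10 * voxel, 10 * voxel, out=grid)
    verts, faces, _, _ = measure.marching_cubes(
        grid, level=0.0, spacing=(spacing,) * 3
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return float(mesh.area), float(abs(mesh.volume))


def structure_descriptors(
    p: CGProtein,
    probe_radius: float = DEFAULT_PROBE_NM,
    voxel: float = DEFAULT_VOXEL_NM,
    scheme: AAClassScheme | None = None,
) -> pd.Series:
    """3D-derived predictors: geometry of the bead union plus surface counts.

    Surface area (nm^2) and volume (nm^3) come from a marching-cubes mesh of
    the signed distance field of the union of bead spheres sampled at
    ``voxel`` pitch; sphericity is pi^(1/3) (6V)^(2/3) / A (1 for a sphere).
    Surface counts use :func:`surface_residues`.
    """
    scheme = scheme or AAClassScheme()
    # marching cubes underestimates both area and volume by O(voxel^2)
    # (inscribed-polyhedron bias); Richardson extrapolation from pitches
    # voxel and voxel/2 cancels the leading error term
    a1, v1 = _mesh_area_volume(p.coords, p.radii, voxel)
    a2, v2 = _mesh_area_volume(p.coords, p.radii, voxel / 2.0)
    area = a2 + (a2 - a1) / 3.0
    volume = v2 + (v2 - v1) / 3.0
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    flags = surface_residues(p, probe_radius=probe_radius)
    surf_letters = [THREE_TO_ONE[c] for c, f in zip(p.residue_codes, flags) if f]
    out: dict[str, float] = {
        "Surface Area": area,
        "Volume": volume,
        "Sphericity": float(sphericity),
        "Surface Residues": float(len(surf_letters)),
    }
    for aa in CANONICAL_AA1:
        out[f"Surface {ONE_TO_THREE[aa]}"] = float(surf_letters.count(aa))
    for name, members in scheme.classes.items():
        out[f"Surface {name}"] = float(
            sum(1 for aa in surf_letters if aa in members)
        )
    return pd.Series(out)


def all_descriptors(
    p: CGProtein,
    probe_radius: float = DEFAULT_PROBE_NM,
    voxel: float = DEFAULT_VOXEL_NM,
    scheme: AAClassScheme | None = None,
) -> pd.Series:
    """Concatenated sequence and structure descriptors for one protein.

    Sequence descriptors are computed on the located residues, matching
    what the structural part sees.
    """
    scheme = scheme or AAClassScheme()
    seq_part = sequence_descriptors(p.located_sequence, scheme)
    struct_part = structure_descriptors(
        p, probe_radius=probe_radius, voxel=voxel, scheme=scheme
    )
    return pd.concat([seq_part, struct_part])
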