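"""Synthetic materials, proteins and training sets.

Everything here is generated, seeded and self-contained: no downloads, no
third-party data.  The two material presets bracket the physics of the real
systems the package targets -- a strongly binding metal-like surface (large
Hamaker constants, deep residue wells) and a weakly binding hydrophilic
oxide-like surface (an order of magnitude smaller Hamaker constants,
shallow or repulsive wells) -- so fixture studies reproduce the qualitative
contrast between the two material classes without shipping any measured
PMF data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CANONICAL_AA3, DAYHOFF_FREQUENCIES
from .descriptors import all_descriptors
from .energy import NPSphere, adsorption_free_energy
from .materials import HamakerTable, MaterialModel, MaterialOptics, PMFTable
from .structure import (
    CGProtein,
    generate_synthetic_protein,
    native_confinement_radius,
)

__all__ = [
    "SyntheticMaterialSpec",
    "gold_like_spec",
    "titania_like_spec",
    "make_material",
    "make_training_set",
    "make_regression_set",
]


@dataclass
class SyntheticMaterialSpec:
    """Parameter ranges for a generated material (all energies kBT, nm)."""

    name: str
    material_index: int
    hamaker_range: tuple[float, float]
    well_depth_range: tuple[float, float]   # negative = attractive
    well_position_range: tuple[float, float] = (0.3, 0.5)
    well_width_range: tuple[float, float] = (0.08, 0.15)
    wall_height: float = 25.0
    wall_decay: float = 0.05
    rc: float = 1.0
    optics: MaterialOptics = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.optics is None:
            self.optics = MaterialOptics(
                name=self.name, refractive_index_550nm=1.5,
                absorption_frequency=3.0e15,
                material_index=self.material_index,
            )


def gold_like_spec() -> SyntheticMaterialSpec:
    """Strong binder: Hamaker constants ~70 kBT, deep adhesive wells."""
    return SyntheticMaterialSpec(
        name="gold-like",
        material_index=0,
        hamaker_range=(50.0, 90.0),
        well_depth_range=(-15.0, -5.0),
        optics=MaterialOptics(
            name="gold-like", refractive_index_550nm=0.4242,
            absorption_frequency=4.87e15, material_index=0, model="drude",
        ),
    )


def titania_like_spec() -> SyntheticMaterialSpec:
    """Weak binder: Hamaker constants ~7 kBT, shallow or repulsive wells."""
    return SyntheticMaterialSpec(
        name="titania-like",
        material_index=1,
        hamaker_range=(5.0, 10.0),
        well_depth_range=(-4.0, 1.0),
        optics=MaterialOptics(
            name="titania-like", refractive_index_550nm=2.5287,
            absorption_frequency=1.50e15, material_index=1,
        ),
    )


def _pmf_curve(spec: SyntheticMaterialSpec, depth: float, d0: float,
               width: float, grid: np.ndarray) -> np.ndarray:
    """Smooth single-well (or single-barrier) curve vanishing at rc.

    Exponential contact wall plus a Gaussian feature at d0; the value at
    the cutoff is subtracted so the tail is exactly zero.
    """
    def raw(d):
        return (spec.wall_height * np.exp(-(d - 0.2) / spec.wall_decay)
                + depth * np.exp(-((d - d0) ** 2) / (2.0 * width**2)))

    return raw(grid) - raw(np.array([spec.rc]))[0]


def make_material(spec: SyntheticMaterialSpec, seed: int = 0) -> MaterialModel:
    """Draw a full MaterialModel (20 Hamaker constants + 20 PMFs) from a spec."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0.05, spec.rc + 1e-9, 0.025)
    hamaker, curves = {}, {}
    for aa in CANONICAL_AA3:
        hamaker[aa] = float(rng.uniform(*spec.hamaker_range))
        depth = float(rng.uniform(*spec.well_depth_range))
        d0 = float(rng.uniform(*spec.well_position_range))
        width = float(rng.uniform(*spec.well_width_range))
        curves[aa] = (grid.copy(), _pmf_curve(spec, depth, d0, width, grid))
    return MaterialModel(
        optics=spec.optics,
        hamaker=HamakerTable(material=spec.name, constants=hamaker),
        pmfs=PMFTable(curves, rc=spec.rc),
        name=spec.name,
    )


def make_training_set(
    n_proteins: int,
    radii,
    materials: list[MaterialModel],
    seed: int = 0,
    n_residues: tuple[int, int] = (40, 90),
    orientations: int = 24,
    dh: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[CGProtein]]:
    """Full pipeline fixture: proteins -> descriptors -> adsorption energies.

    Generates ``n_proteins`` synthetic chains, computes their descriptor
    vectors once, then evaluates the adsorption free energy for every
    (protein, material, radius) combination.  Returns the descriptor matrix
    (one row per combination), a metadata frame (protein id, material name
    and index, R, ln R, energies in kBT and scaled by <A_NP>), and the
    protein list.  Deterministic under ``seed``.
    """
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    radii = list(radii)
    rng = np.random.default_rng(seed)
    proteins, descriptor_rows = [], []
    for i in range(n_proteins):
        n_res = int(rng.integers(n_residues[0], n_residues[1] + 1))
        p = generate_synthetic_protein(
            n_res, seed=int(rng.integers(0, 2**31 - 1)),
            confinement_radius=native_confinement_radius(n_res),
        )
        proteins.append(p)
        descriptor_rows.append(all_descriptors(p))

    X_rows, meta_rows = [], []
    for p, desc in zip(proteins, descriptor_rows):
        for mat in materials:
            avg_A = mat.average_hamaker
            for R in radii:
                res = adsorption_free_energy(
                    p, NPSphere(mat, R), grid=orientations, dh=dh
                )
                X_rows.append(desc)
                meta_rows.append(
                    dict(protein=p.id, material=mat.name,
                         material_index=mat.optics.material_index,
                         R_nm=R, ln_R=float(np.log(R)),
                         E_kT=res.boltzmann_average,
                         E_scaled=res.boltzmann_average / avg_A)
                )
    X = pd.DataFrame(X_rows).reset_index(drop=True)
    meta = pd.DataFrame(meta_rows)
    return X, meta, proteins


def make_regression_set(
    n_samples: int = 600,
    seed: int = 0,
    n_descriptors: int = 12,
    k_active: int = 3,
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor/energy rows with a known smooth generating function.

    Latent factors z1..z_{k_active} (decreasing variance) are mixed into
    ``n_descriptors`` correlated descriptor columns; the dimensionless
    target is a smooth nonlinear function of the latents, the material
    index and ln R, plus Gaussian noise.  Because the descriptors are exact
    linear mixtures, PCA recovers the latents and an adequate network can
    reach high validation R^2 -- which is what makes this set a metamodel
    recovery oracle.
    """
    if k_active < 1 or k_active > 3:
        raise ValueError("k_active must be 1..3")
    rng = np.random.default_rng(seed)
    scales = np.array([2.0, 1.2, 0.8])[:k_active]
    z = rng.normal(size=(n_samples, k_active)) * scales
    mixing = rng.normal(size=(k_active, n_descriptors))
    X = z @ mixing + 0.05 * rng.normal(size=(n_samples, n_descriptors))
    X = pd.DataFrame(
        X, columns=[f"Descriptor {i + 1:02d}" for i in range(n_descriptors)]
    )

    material = rng.integers(0, 2, size=n_samples).astype(float)
    R = np.exp(rng.uniform(np.log(5.0), np.log(200.0), size=n_samples))
    ln_R = np.log(R)

    g = -(1.0 + 0.9 * np.tanh(z[:, 0] / scales[0]))
    if k_active >= 2:
        g = g - 0.5 * np.sin(z[:, 1] / scales[1])
    if k_active >= 3:
        g = g - 0.3 * np.tanh(z[:, 2] / scales[2])
    g = g * (0.6 + 0.4 * ln_R / np.log(200.0)) * (1.6 - 0.8 * material)
    y = g + noise_sd * rng.normal(size=n_samples)

    meta = pd.DataFrame(
        dict(material_index=material, R_nm=R, ln_R=ln_R,
             E_scaled=y, E_true=g)
    )
    return X, meta
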