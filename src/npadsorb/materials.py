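"""Material data and the two analytic amino-acid/nanoparticle interaction terms.

The long-range attraction between a residue bead and the nanoparticle bulk is
a two-sphere van der Waals (Hamaker) potential.  At short range the bead
instead feels a tabulated potential of mean force (PMF) for that residue on
the flat material surface, precomputed atomistically and consumed here as
distance-energy tables.  Because the PMF already contains the interaction
with the material lying within its cutoff ``rc`` of the bead, the Hamaker
term at short range must have the contribution of that "lens" of
nanoparticle volume subtracted to avoid double counting.

All energies are in units of kBT at 300 K; all lengths in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import integrate
from scipy.interpolate import PchipInterpolator

from .constants import (
    CANONICAL_AA3,
    DAYHOFF_FREQUENCIES,
    KT_JOULE,
    ONE_TO_THREE,
    PLANCK_J_S,
    canonical_three,
)

__all__ = [
    "MaterialOptics",
    "HamakerTable",
    "PMFTable",
    "MaterialModel",
    "WATER_OPTICS",
    "load_aa_optics",
    "hamaker_constant_from_optics",
    "core_potential_far",
    "core_potential_near",
    "lens_correction",
    "pmf_energy",
    "average_hamaker",
    "load_material",
    "save_material",
]

#: Default PMF cutoff (nm) when a data set does not state one.
DEFAULT_RC_NM = 1.0


# ---------------------------------------------------------------------------
# Optical models and Hamaker constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialOptics:
    """Optical data needed for a Hamaker-constant estimate.

    ``model`` selects how the permittivity at imaginary frequency is built:
    ``"oscillator"`` treats the medium as a single UV oscillator
    parameterised by the visible refractive index and absorption frequency
    (the Tabor-Winterton picture, appropriate for dielectrics such as
    anatase or amino acids), while ``"drude"`` treats it as a free-electron
    metal whose ``absorption_frequency`` plays the role of the plasma
    frequency (appropriate for gold).
    """

    name: str
    refractive_index_550nm: float
    absorption_frequency: float  # Hz
    material_index: int = 0      # categorical: 0 gold-like, 1 titania-like
    model: str = "oscillator"
    static_permittivity: float | None = None

    def __post_init__(self):
        if self.refractive_index_550nm <= 0 or self.absorption_frequency <= 0:
            raise ValueError("refractive index and absorption frequency must be > 0")
        if self.material_index not in (0, 1):
            raise ValueError("material_index must be 0 or 1")
        if self.model not in ("oscillator", "drude"):
            raise ValueError(f"unknown optical model {self.model!r}")

    def epsilon_imag_freq(self, nu: np.ndarray) -> np.ndarray:
        """Permittivity along the imaginary frequency axis, eps(i*nu)."""
        nu = np.asarray(nu, dtype=float)
        if self.model == "drude":
            return 1.0 + (self.absorption_frequency / nu) ** 2
        n2 = self.refractive_index_550nm**2
        return 1.0 + (n2 - 1.0) / (1.0 + (nu / self.absorption_frequency) ** 2)

    def epsilon_static(self) -> float:
        if self.static_permittivity is not None:
            return self.static_permittivity
        if self.model == "drude":
            return np.inf
        return self.refractive_index_550nm**2


def load_aa_optics(path=None) -> dict[str, MaterialOptics]:
    """Per-residue optical constants from an editable TSV.

    The packaged default file carries synthetic representative values
    (typical organic-matter refractive indices and UV frequencies); swap in
    measured constants by pointing ``path`` at your own file with columns
    residue, n550, nu0_hz, eps_static.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "aa_optics_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples():
        aa = canonical_three(row.residue)
        out[aa] = MaterialOptics(
            name=aa,
            refractive_index_550nm=float(row.n550),
            absorption_frequency=float(row.nu0_hz),
            static_permittivity=float(row.eps_static),
        )
    missing = set(CANONICAL_AA3) - set(out)
    if missing:
        raise ValueError(f"optics file missing residues: {sorted(missing)}")
    return out


WATER_OPTICS = MaterialOptics(
    name="water",
    refractive_index_550nm=1.333,
    absorption_frequency=3.0e15,
    material_index=0,
    model="oscillator",
    static_permittivity=80.1,
)


def _delta(eps_a: np.ndarray, eps_b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        out = (eps_a - eps_b) / (eps_a + eps_b)
    return np.where(np.isinf(eps_a), 1.0, out)


def hamaker_constant_from_optics(
    np_optics: MaterialOptics,
    aa_optics: MaterialOptics,
    water_optics: MaterialOptics = WATER_OPTICS,
    n_matsubara: int = 4000,
) -> float:
    """Non-retarded Hamaker constant A123 across water, in kBT.

    First-order Lifshitz estimate: the zero-frequency (entropic) term plus
    the discrete Matsubara sum over imaginary frequencies,

        A = (3/4) kBT d1(0) d2(0) + (3/2) kBT sum_{m>=1} d1(i nu_m) d2(i nu_m),

    with d_j = (eps_j - eps_w)/(eps_j + eps_w) and nu_m = 2 pi m kBT / h.
    For two identical single-oscillator media this reduces to the familiar
    Tabor-Winterton expression.  The result is symmetric in the two outer
    media.
    """
    nu1 = 2.0 * np.pi * KT_JOULE / PLANCK_J_S  # first Matsubara frequency, Hz
    nus = nu1 * np.arange(1, n_matsubara + 1)

    d1_0 = _delta(np.asarray(np_optics.epsilon_static()),
                  np.asarray(water_optics.epsilon_static()))
    d2_0 = _delta(np.asarray(aa_optics.epsilon_static()),
                  np.asarray(water_optics.epsilon_static()))
    zero_term = 0.75 * float(d1_0) * float(d2_0)

    eps_w = water_optics.epsilon_imag_freq(nus)
    d1 = _delta(np_optics.epsilon_imag_freq(nus), eps_w)
    d2 = _delta(aa_optics.epsilon_imag_freq(nus), eps_w)
    dispersion = 1.5 * float(np.sum(d1 * d2))
    return zero_term + dispersion


# ---------------------------------------------------------------------------
# Hamaker core potential (two spheres)
# ---------------------------------------------------------------------------

def core_potential_far(R, R_AA, D, A123):
    """Hamaker potential of two non-overlapping spheres, kBT.

    Classical volume-integrated London result for spheres of radii ``R``
    (nanoparticle) and ``R_AA`` (bead) at centre-centre distance ``D``:

        U = -(A/6) [ 2 R R'/(D^2-(R+R')^2) + 2 R R'/(D^2-(R-R')^2)
                     + ln( (D^2-(R+R')^2) / (D^2-(R-R')^2) ) ]

    evaluated in a cancellation-safe form so the -(16/9) A R^3 R'^3 / D^6
    far-field asymptote is reproduced even at D >> R.  Always <= 0 for
    positive ``A123``; tends to 0 as D grows.
    """
    R, R_AA, D = np.asarray(R, float), np.asarray(R_AA, float), np.asarray(D, float)
    if np.any(D <= R + R_AA):
        raise ValueError("spheres overlap: require D > R + R_AA")
    y1 = ((R + R_AA) / D) ** 2
    y2 = ((R - R_AA) / D) ** 2
    t1 = 2.0 * R * R_AA / (D * D) / (1.0 - y1)
    t2 = 2.0 * R * R_AA / (D * D) / (1.0 - y2)
    t3 = np.log1p(-y1) - np.log1p(-y2)
    return -(np.asarray(A123, float) / 6.0) * (t1 + t2 + t3)


def _sphere_kernel(r2: np.ndarray, a: float) -> np.ndarray:
    """Exact r^-6 London integral of a sphere of radius ``a`` against a
    point at squared distance ``r2`` from its centre (r > a)."""
    return (4.0 * np.pi * a**3 / 3.0) / (r2 - a * a) ** 3


def lens_correction(R, R_AA, D, A123, rc):
    """Hamaker energy (kBT, <= 0) of the bead with the lens of nanoparticle
    volume lying within ``rc`` of the bead centre.

    This is the piece of the bulk already represented by the surface PMF.
    Evaluated by reducing the bead-lens London integral to a 1-D radial
    quadrature using the exact sphere-point kernel.  Zero when the bead
    centre is farther than ``rc`` from the surface (empty lens), which makes
    the corrected core potential continuous at the PMF cutoff.
    """
    R, R_AA, D, rc = float(R), float(R_AA), float(D), float(rc)
    if D <= R:
        raise ValueError("bead centre inside the nanoparticle (D <= R)")
    lo = D - R
    if lo >= rc:
        return 0.0
    if lo <= R_AA:
        raise ValueError("bead overlaps the nanoparticle surface (D - R <= R_AA)")

    def integrand(r):
        mu = np.clip((D * D + r * r - R * R) / (2.0 * D * r), -1.0, 1.0)
        return r * r * (1.0 - mu) * _sphere_kernel(r * r, R_AA)

    val, _ = integrate.quad(integrand, lo, rc, epsabs=1e-13, epsrel=1e-10, limit=200)
    return -(A123 / np.pi**2) * 2.0 * np.pi * val


def core_potential_near(R, R_AA, D, A123, rc):
    """Short-range branch of the core potential: the full two-sphere Hamaker
    energy minus the lens already counted by the surface PMF.  Reduces to
    :func:`core_potential_far` when the lens is empty (``D - R >= rc``)."""
    base = float(core_potential_far(R, R_AA, D, A123))
    return base - lens_correction(R, R_AA, D, A123, rc)


from functools import lru_cache


@lru_cache(maxsize=4096)
def get_core_table(R: float, R_AA: float, rc: float) -> "CorePotentialTable":
    """Cached core-potential table; geometry repeats across proteins and
    orientations, so the quadrature cost is paid once per (R, R_AA, rc)."""
    return CorePotentialTable(R, R_AA, rc)


class CorePotentialTable:
    """Vectorised core potential for one (nanoparticle radius, bead radius).

    The near branch is precomputed on a contact-refined grid of surface
    separations (per unit Hamaker constant) and interpolated; the far branch
    uses the closed form directly.  Used by the energy engine, where the
    same geometry is evaluated for thousands of bead placements.
    """

    def __init__(self, R: float, R_AA: float, rc: float, n_grid: int = 160):
        self.R, self.R_AA, self.rc = float(R), float(R_AA), float(rc)
        eps = max(1e-4, 1e-3 * R_AA)
        # sqrt spacing concentrates points at contact, where U varies fastest
        t = np.linspace(np.sqrt(eps), np.sqrt(self.rc - self.R_AA), n_grid) ** 2
        d = self.R_AA + t
        u = np.array([core_potential_near(R, R_AA, R + di, 1.0, rc) for di in d])
        self._near = PchipInterpolator(d, u, extrapolate=True)
        self._d_min = d[0]

    def __call__(self, separation: np.ndarray, A123: float) -> np.ndarray:
        """Core potential at bead-surface separations ``separation`` (nm)."""
        d = np.asarray(separation, dtype=float)
        out = np.zeros_like(d)
        near = d < self.rc
        far = ~near
        if np.any(far):
            out[far] = core_potential_far(self.R, self.R_AA, self.R + d[far], A123)
        if np.any(near):
            dn = np.clip(d[near], self._d_min, None)
            out[near] = A123 * self._near(dn)
        return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class HamakerTable:
    """Per-residue Hamaker constants (kBT) for one nanomaterial."""

    material: str
    constants: dict[str, float]

    def __post_init__(self):
        self.constants = {canonical_three(k): float(v) for k, v in self.constants.items()}
        missing = set(CANONICAL_AA3) - set(self.constants)
        if missing:
            raise ValueError(f"Hamaker table missing residues: {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.constants.values()):
            raise ValueError("Hamaker constants must be finite")

    def __getitem__(self, aa: str) -> float:
        return self.constants[canonical_three(aa)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.constants.items()), columns=["residue", "A123_kT"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, material: str = "") -> "HamakerTable":
        df = pd.read_csv(path, sep="\t")
        return cls(material=material or str(path),
                   constants=dict(zip(df["residue"], df["A123_kT"])))


class PMFTable:
    """Tabulated residue-surface potentials of mean force for one material.

    Each residue has a sampled curve of energy (kBT) against bead-surface
    separation (nm) on a strictly increasing grid reaching the cutoff
    ``rc``, where the energy must have decayed to zero.  Queries use
    monotone-cubic (PCHIP) interpolation, return exactly zero beyond the
    cutoff, and clamp to the innermost tabulated value below the grid --
    PMFs diverge at contact, so extrapolating inward would be unsafe.
    """

    def __init__(self, curves: dict[str, tuple[np.ndarray, np.ndarray]],
                 rc: float = DEFAULT_RC_NM, tail_tol: float = 0.05):
        self.rc = float(rc)
        self.curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for aa, (grid, energy) in curves.items():
            aa = canonical_three(aa)
            grid = np.asarray(grid, dtype=float)
            energy = np.asarray(energy, dtype=float)
            if grid.ndim != 1 or grid.shape != energy.shape:
                raise ValueError(f"{aa}: grid and energy shapes differ")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{aa}: separation grid must be strictly increasing")
            if grid[0] <= 0 or grid[-1] < self.rc - 1e-9:
                raise ValueError(f"{aa}: grid must cover (0, rc]")
            if abs(energy[-1]) > tail_tol:
                raise ValueError(
                    f"{aa}: PMF does not vanish at the cutoff "
                    f"(U(rc) = {energy[-1]:.3f} kBT)"
                )
            self.curves[aa] = (grid, energy)
        self._interp: dict[str, PchipInterpolator] = {}
        self._warned_below: set[str] = set()

    def residues(self) -> list[str]:
        return sorted(self.curves)

    def energy(self, aa: str, separation) -> np.ndarray:
        """PMF energy (kBT) at the given surface separations (nm)."""
        aa = canonical_three(aa)
        if aa not in self.curves:
            raise KeyError(f"no PMF for residue {aa}")
        if aa not in self._interp:
            grid, en = self.curves[aa]
            self._interp[aa] = PchipInterpolator(grid, en, extrapolate=False)
        grid, en = self.curves[aa]
        sep = np.asarray(separation, dtype=float)
        scalar = sep.ndim == 0
        sep = np.atleast_1d(sep)
        if np.any(sep < 0):
            raise ValueError("separation must be >= 0")
        out = np.zeros_like(sep)
        inside = sep <= self.rc
        below = sep < grid[0]
        if np.any(below) and aa not in self._warned_below:
            warnings.warn(
                f"{aa}: separation below tabulated PMF range; clamping to the "
                f"innermost grid value"
            )
            self._warned_below.add(aa)
        mid = inside & ~below
        out[mid] = self._interp[aa](np.clip(sep[mid], grid[0], grid[-1]))
        out[below] = en[0]
        return out[0] if scalar else out


def pmf_energy(table: PMFTable, aa: str, surface_separation) -> float | np.ndarray:
    """Functional wrapper around :meth:`PMFTable.energy`."""
    return table.energy(aa, surface_separation)


@dataclass
class MaterialModel:
    """Everything needed to evaluate one nanomaterial against a protein."""

    optics: MaterialOptics
    hamaker: HamakerTable
    pmfs: PMFTable
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = self.optics.name
        missing = set(CANONICAL_AA3) - set(self.pmfs.curves)
        if missing:
            raise ValueError(f"PMF table missing residues: {sorted(missing)}")

    @property
    def rc(self) -> float:
        return self.pmfs.rc

    @property
    def average_hamaker(self) -> float:
        """Dayhoff-weighted mean Hamaker constant <A_NP>, kBT."""
        return average_hamaker(self.hamaker, DAYHOFF_FREQUENCIES)


def average_hamaker(table: HamakerTable, weights: dict[str, float]) -> float:
    """Frequency-weighted mean of the per-residue Hamaker constants.

    ``weights`` maps residues (one- or three-letter codes) to non-negative
    weights, typically background amino-acid frequencies.
    """
    total_w = 0.0
    total = 0.0
    for aa, w in weights.items():
        aa3 = canonical_three(ONE_TO_THREE.get(aa, aa))
        if w < 0:
            raise ValueError("weights must be non-negative")
        if aa3 not in table.constants:
            raise ValueError(f"residue {aa3} missing from Hamaker table")
        total += table.constants[aa3] * w
        total_w += w
    if total_w == 0:
        raise ValueError("weights sum to zero")
    return total / total_w


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def save_material(model: MaterialModel, directory) -> Path:
    """Write a material as manifest.yaml + hamaker.tsv + pmf/<AA3>.tsv."""
    directory = Path(directory)
    (directory / "pmf").mkdir(parents=True, exist_ok=True)
    model.hamaker.to_tsv(directory / "hamaker.tsv")
    pmf_files = {}
    for aa, (grid, en) in model.pmfs.curves.items():
        rel = f"pmf/{aa}.tsv"
        pd.DataFrame({"separation_nm": grid, "energy_kT": en}).to_csv(
            directory / rel, sep="\t", index=False, float_format="%.8g"
        )
        pmf_files[aa] = rel
    manifest = {
        "schema_version": 1,
        "name": model.name,
        "rc_nm": model.rc,
        "optics": {
            "refractive_index_550nm": model.optics.refractive_index_550nm,
            "absorption_frequency_hz": model.optics.absorption_frequency,
            "material_index": model.optics.material_index,
            "model": model.optics.model,
            "static_permittivity": model.optics.static_permittivity,
        },
        "hamaker_file": "hamaker.tsv",
        "pmf_files": pmf_files,
    }
    path = directory / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_material(manifest_path) -> MaterialModel:
    """Load a material written by :func:`save_material`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"material manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    opt = manifest["optics"]
    optics = MaterialOptics(
        name=manifest["name"],
        refractive_index_550nm=float(opt["refractive_index_550nm"]),
        absorption_frequency=float(opt["absorption_frequency_hz"]),
        material_index=int(opt["material_index"]),
        model=opt.get("model", "oscillator"),
        static_permittivity=opt.get("static_permittivity"),
    )
    hamaker = HamakerTable.from_tsv(base / manifest["hamaker_file"],
                                    material=manifest["name"])
    curves = {}
    for aa, rel in manifest["pmf_files"].items():
        df = pd.read_csv(base / rel, sep="\t")
        curves[aa] = (df["separation_nm"].to_numpy(), df["energy_kT"].to_numpy())
    pmfs = PMFTable(curves, rc=float(manifest["rc_nm"]))
    return MaterialModel(optics=optics, hamaker=hamaker, pmfs=pmfs,
                         name=manifest["name"])
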