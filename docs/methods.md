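# Methods

## Coarse-graining

Each residue is one bead at its α-carbon. Bead radii are the radii of
spheres with the residue's mean volume (Zamyatnin tabulation), 0.24 nm for
glycine up to 0.38 nm for tryptophan; the same radii serve the hard wall in
the energy engine and the geometry descriptors. The PDB occupancy αᵢ of the
CA atom weights the bead's contribution to every energy sum. When a residue
has alternate locations the highest-occupancy conformer is kept together
with its occupancy — a single-site bead cannot host two positions, and the
dominant conformer is the best single-point summary. Selenomethionine is
read as methionine. Missing residues stay in the sequence but get no bead;
the located/missing mask is reconstructed by globally aligning the observed
residues to SEQRES (match +1, mismatch 0, gap open −10, extend −0.5,
leftmost optimal alignment). Coordinates are stored in nm; RMSDs are
reported in Å because that is how structure-comparison results are usually
read.

Masking a predicted structure against an experimental reference keeps
exactly those model beads whose aligned reference position is located, so
both structures contain the same residue set before RMSD or energy
comparison. Pairs aligning below 50% identity are refused — in practice
that always means mispaired files, and silently masking would produce a
meaningless comparison.

## Interaction model

The energy of a bead at centre distance D from a particle of radius R is
the sum of a short-range surface term and a long-range bulk term.

**Surface term.** Per-residue PMFs against the flat material surface are
consumed as tabulated separation–energy curves and interpolated
monotone-cubically (PCHIP, no overshoot). Beyond the cutoff r_c the energy
is exactly zero; below the innermost grid point the value is clamped to
the innermost tabulated energy (with a warning) because PMFs diverge at
contact and polynomial extrapolation there is unsafe. The curves are
treated as flat-surface potentials evaluated at the bead–surface
separation D − R, with no explicit curvature correction: the curvature
effect on a sub-nanometre-range potential is far smaller than the
uncertainty of the PMFs themselves, and this choice keeps one table valid
for all radii. r_c defaults to 1.0 nm and is configurable per material.

**Bulk term.** The classical Hamaker two-sphere potential (volume
integral of the London r⁻⁶ kernel). It is evaluated in a
cancellation-safe form (`log1p` on the small ratios): the naive expression
loses all significant digits by D ≈ 100(R+R′), where the potential is the
tiny residual of three nearly cancelling ~10⁻⁵ terms, and would miss the
−(16/9)AR³R′³/D⁶ asymptote by several percent.

**Lens correction.** Within r_c of the surface the PMF already contains
the interaction with the nearby particle material, so the bulk term must
exclude it. The excluded region is the lens where the particle sphere
intersects the ball of radius r_c around the bead centre. Its energy is
computed exactly: the London integral of the bead sphere against a point
has the closed form (4πR′³/3)/(r²−R′²)³, and integrating it over the lens
reduces, by azimuthal symmetry, to a one-dimensional radial quadrature.
The correction vanishes continuously as the bead leaves the PMF range, so
the two branches of the bulk term join continuously at r_c. The
subtraction also removes the contact divergence of the bulk term — what
remains is the interaction with material at least r_c − R′ away from the
bead surface, which is bounded. A validation oracle integrates the same
lens in particle-centred coordinates (an independent parametrisation) and
agrees to better than 1%; a Cartesian Monte-Carlo integral agrees within
its sampling error. For speed the near branch is precomputed per
(R, bead radius, r_c) on a contact-refined grid and interpolated; tables
are cached process-wide because the same geometry recurs for every
orientation and every protein.

Electrostatics is deliberately absent: the model targets the
dispersion-plus-surface-chemistry regime, and a screened-Coulomb term
would require per-system ionic conditions that the data model does not
carry.

**Hamaker constants from optics.** The primary path is tabulated
per-residue constants (TSV). When only optical data are available, A₁₂₃
across water is estimated to first order in the dielectric contrasts as
the zero-frequency (entropic) term plus a discrete Matsubara sum,
Δⱼ = (εⱼ−ε_w)/(εⱼ+ε_w) evaluated along the imaginary frequency axis.
Dielectrics use the single-oscillator model built from n(550 nm) and the
UV absorption frequency ν₀ — for two identical oscillators this reduces to
the familiar Tabor–Winterton expression. Metals cannot be represented by
that oscillator (their visible refractive index is below water's, which
would flip the sign of the attraction); they use a Drude permittivity with
ν₀ as the plasma frequency, which correctly makes the metal constant much
larger than an oxide's against the same residue. The per-residue optical
constants shipped in `data/aa_optics_synthetic.tsv` are synthetic
representative values (organic-matter refractive indices, UV frequencies
near 3·10¹⁵ Hz) intended as editable placeholders, not measurements —
quantitative work should supply a Hamaker table directly.

## Free-energy reduction

For one orientation the 1-D configurational integral over h runs against a
uniform reference measure on [h_min, h_max]: F = −ln[(1/L)∫e^(−U)dh] by
trapezoidal quadrature with Δh = 0.05 nm (fine enough to resolve PMF wells
of width ≳ 0.08 nm). h_max is the protein extent plus r_c plus 2 nm of
headroom, so U has decayed to ≲10⁻³ kBT there; configurations with any
bead closer than its radius to the surface are a hard wall (zero weight).
Because the reference measure is a convention, absolute energies carry a
state-definition constant; differences and rankings are the robust
outputs.

Orientations are a Fibonacci lattice on the sphere with equal weights —
deterministic, quasi-uniform, and refinable by a single count parameter
(default 64). The orientation (φ, θ) is applied as Ry(θ)·Rz(φ) about the
centre of mass, which makes the particle direction seen from the protein
frame sweep the whole sphere; the Boltzmann combination is evaluated in
shifted (overflow-safe) form. The three summaries always satisfy
min ≤ Boltzmann ≤ mean.

Convergence with orientation count depends on the material. For the
weakly binding preset the landscape is smooth and doubling the grid from
512 points changes E_ads by < 0.1 kBT. For strongly adhesive materials the
Boltzmann average is dominated by narrow, deep minima (tens of kBT below
the mean); resolving them is a quadrature problem with no cheap fix, and
E_ads is then effectively a best-orientation estimate whose residual
grid sensitivity (a few kBT at default settings) should be kept in mind
when comparing absolute values. Convergence assertions in the test suite
therefore use the weak-binding material, where the quadrature error is
actually measurable.

## Descriptors

Sequence descriptors follow EMBOSS pepstats: average-isotope molecular
weight, residue counts and molar fractions, class fractions (tiny, small,
aliphatic, aromatic, non-polar, polar, charged, basic, acidic — EMBOSS
definitions restricted to the canonical 20), and a Henderson–Hasselbalch
net charge at pH 7 with EMBOSS pKa values. Structure descriptors are
computed on the bead model, not an atomistic surface, because bead
coordinates are all the pipeline guarantees: surface detection is
Shrake–Rupley with a 0.14 nm water probe on probe-expanded bead spheres
(128 golden-spiral test points per bead), and surface area/volume come
from a marching-cubes mesh of the signed-distance field of the bead union
at 0.1 nm pitch. Marching cubes on a linear field underestimates both
area and volume by O(pitch²) (inscribed-polyhedron bias) — about 10% in
volume for a single 0.24 nm bead — so both are Richardson-extrapolated
from pitches h and h/2, which brings the single-sphere error to ~0.1% and
makes the 0.1 → 0.05 nm refinement change well under 2%. Sphericity is
π^(1/3)(6V)^(2/3)/A. The descriptor registry is a named mapping, so extra
predictors can be added without touching the consumers.

## Ranking statistics

The Kendall coefficient is computed from the discordant-pair count d_K
(equal to the minimal number of adjacent swaps, counted by merge-sort
inversion counting) and normalised as τ = 1 − 4d_K/(N(N−1)): +1 for
identical orderings, −1 for a reversal, ≈0 for unrelated lists. For untied
data this coincides with τ-a, and the implementation is cross-checked
against both brute-force bubble-sort counting and the SciPy statistic.
Energies are continuous so ties are measure-zero; deterministic
lexicographic tie-breaking keeps rankings reproducible anyway. Agreement
between two energy sets is summarised by an OLS fit with intercept (R²,
slope) plus per-pair relative errors with the reference set in the
denominator.

## Metamodel

Descriptors are z-scored and rotated by PCA; the top k component scores,
the material index (0 metal-like, 1 oxide-like) and ln(R/nm) feed an
ensemble of feed-forward networks trained on energies divided by the
material's Dayhoff-weighted mean Hamaker constant ⟨A_NP⟩ — the scaling
puts strongly and weakly binding materials on a comparable dimensionless
range, and multiplying predictions by ⟨A_NP⟩ restores kBT exactly. A
random two-thirds/one-third split is recorded for validation; each
ensemble member trains on an independent bootstrap resample of the
training rows. The ensemble mean is the prediction, the ensemble standard
deviation the uncertainty.

The network internals are necessarily a fresh choice (surrogates of this
kind are usually built with automated tools that hide them): depth hidden
layers of 16 tanh units, Adam, early stopping on a 10% inner holdout.
Defaults — depth 4, k = 3, 30 networks, 2/3 training fraction — sit at the
plateau of the brute-force (depth, k) scan on the recovery fixture, where
R² saturates once all active components are included; the scan's
recommended cell is the smallest (depth, k) within 0.02 of the best, the
usual guard against overfitting. All randomness (split, bootstrap,
initialisation) derives from one master seed. Models serialise to
versioned JSON with weights inline, so a saved model reloads bit-exactly
with no pickle dependency.

## Synthetic data

The fixture generator emulates the study conditions end to end without any
external data. Proteins are self-avoiding random walks with the 0.38 nm
CA–CA step and a 0.36 nm excluded-volume floor, residues drawn from
Dayhoff background frequencies, optionally confined to a sphere to make
compact globules. The recommended confinement
(`native_confinement_radius`, 0.42·n^(1/3) nm) reproduces the ~0.13 nm³
per residue packing density of folded proteins; this matters physically,
because loosely confined walks develop concave, crescent-like shapes that
can genuinely bind a small particle *more* strongly than a large one by
wrapping around it — a curvature-matching effect that compact convex
globules, like most real proteins, do not show. Radius-trend measurements
therefore use native-density fixtures and ≥256 orientations, so the
~1 kBT quadrature noise stays small against the trend being measured. Materials come in two presets chosen to bracket the real
contrast between a noble metal and a hydrophilic oxide: per-residue
Hamaker constants uniform in 50–90 kBT with deep adhesive wells (−15 to
−5 kBT) for the metal-like preset, 5–10 kBT with shallow-to-repulsive
wells (−4 to +1 kBT) for the oxide-like one — an order of magnitude apart
in dispersion strength, and weakly vs strongly hydrated at contact. PMF
curves are an exponential contact wall plus a Gaussian well at 0.3–0.5 nm,
pinned to exactly zero at r_c; smooth, single-featured, and with an
analytically known minimum, which is what the interpolation tests need.

The regression fixture for the metamodel mixes k latent factors linearly
into twelve correlated descriptor columns and generates the dimensionless
energy as a smooth bounded function of the latents, the material index and
ln R plus Gaussian noise (σ = 0.1) — so PCA provably recovers the inputs
and "the model learned the generating function" is a well-defined, checkable
statement (validation R² ≈ 0.97 at n = 600).

What the synthetic data does not emulate: real secondary structure (walks
at native density still lack helices, sheets and the smoother surfaces
they produce), correlated PMF shapes across residues of similar chemistry,
sequence composition of any particular proteome, and measured material
tables. Passing tests therefore demonstrate the correctness and internal
consistency of the machinery — parsing, physics, reduction, statistics,
learning — not agreement with laboratory adsorption data; quantitative
claims about a real material require its measured PMF and Hamaker tables
on the documented TSV/YAML interface.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances — 40–100-residue proteins, 8–64 orientations for routine energies
(512–1024 where convergence itself is measured), 10 perturbation
replicates, 600-row training sets — chosen so the full suite completes in
about a minute while every assertion still measures the property it names
at useful statistical power.

## Known limitations

Rigid proteins; spherical particles only; no electrostatics; no
orientation-dependent PMF curvature correction; absolute E_ads carries the
reference-state constant of the h-integral; strongly adhesive materials
retain a few kBT of orientation-quadrature sensitivity at default grids;
the optics-based Hamaker route is a first-order estimate with placeholder
residue optics, intended for ordering and scale, not precision.
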