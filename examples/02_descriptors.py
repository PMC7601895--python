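"""Sequence- and structure-derived predictors for one protein.

Computes the pepstats-style sequence descriptors plus bead-model geometry
(surface area, volume, sphericity) and surface-residue counts.
"""

from npadsorb import all_descriptors, generate_synthetic_protein
from npadsorb.structure import native_confinement_radius

protein = generate_synthetic_protein(80, seed=3, confinement_radius=native_confinement_radius(80))
d = all_descriptors(protein)

for key in ["Molecular Weight", "Net Charge pH7", "Molar Fraction Charged",
            "Surface Area", "Volume", "Sphericity", "Surface Residues",
            "Surface GLU", "Surface LYS"]:
    print(f"{key:>24}: {d[key]:.3f}")

# Molecular weight is in Da, area in nm^2, volume in nm^3; sphericity is 1
# for a perfect sphere and drops as the fold elongates.  Surface counts say
# how many residues of each kind a nanoparticle could actually touch.
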