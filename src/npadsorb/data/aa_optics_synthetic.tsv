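# Synthetic representative optical constants for the 20 canonical amino acids.
# These are plausible dielectric-range placeholders (editable), not measured
# values: visible refractive indices near those of dry organic matter, with
# aromatic residues slightly higher, and UV absorption frequencies near 3e15 Hz.
residue	n550	nu0_hz	eps_static
ALA	1.530	3.00e15	2.6
ARG	1.560	2.95e15	3.2
ASN	1.550	2.95e15	3.0
ASP	1.550	2.95e15	3.0
CYS	1.565	2.90e15	2.9
GLN	1.550	2.95e15	3.0
GLU	1.550	2.95e15	3.0
GLY	1.520	3.05e15	2.5
HIS	1.590	2.80e15	3.1
ILE	1.525	3.05e15	2.5
LEU	1.525	3.05e15	2.5
LYS	1.545	3.00e15	3.0
MET	1.560	2.90e15	2.8
PHE	1.600	2.75e15	2.7
PRO	1.540	3.00e15	2.6
SER	1.537	3.00e15	2.8
THR	1.535	3.00e15	2.8
TRP	1.620	2.70e15	2.9
TYR	1.610	2.75e15	2.9
VAL	1.525	3.05e15	2.5
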