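# Per-residue property scales: one row per scale, 20 value columns A..Y
# (one-letter codes, alphabetical). Rows with empty value cells are
# registered as placeholders and cannot be used for computation until a
# user fills in the 20 values. This file is user-editable.
#
# mant_hydrophobicity: RPLC retention-time hydrophobicity coefficients (h);
#   the total hydrophobicity H_T of a hexapeptide is the sum of its six h.
# isoelectric_point: Zimmerman pI values (external literature scale).
# long_range_energy_synthetic: SYNTHETIC stand-in for a long-range
#   non-bonded (contact) energy scale whose published values are not
#   bundled; constructed to rank residues by burial tendency. Replace with
#   a real scale for production use.
scale	description	units	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
mant_hydrophobicity	RPLC retention-time hydrophobicity coefficients	min	13.26	26.84	8.15	11.12	90.17	3.80	4.14	69.53	2.92	73.84	51.64	1.00	27.54	6.00	10.24	3.53	11.64	44.60	100.00	47.49
isoelectric_point	Isoelectric point of free amino acids (Zimmerman)	pH	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66
long_range_energy_synthetic	Synthetic stand-in long-range non-bonded energy scale	kcal/mol	0.60	0.81	0.44	0.45	0.91	0.58	0.60	0.88	0.36	0.85	0.79	0.47	0.46	0.45	0.41	0.55	0.59	0.84	0.80	0.70
K0	Compressibility (placeholder; values not bundled)	-
Ht	Thermodynamic transfer hydrophobicity (placeholder)	-
Hp	Surrounding hydrophobicity (placeholder)	-
P	Polarity (placeholder)	-
pHi	Isoelectric point (placeholder)	-
pK	Side-chain pK (placeholder)	-
Mw	Molecular weight (placeholder)	-
Bl	Bulkiness (placeholder)	-
Rf	Chromatographic index (placeholder)	-
mu	Refractive index (placeholder)	-
Hnc	Normalized consensus hydrophobicity (placeholder)	-
Esm	Short/medium-range non-bonded energy (placeholder)	-
El	Long-range non-bonded energy (placeholder)	-
Et	Total non-bonded energy (placeholder)	-
P_alpha	Alpha-helical propensity (placeholder)	-
P_beta	Beta-strand propensity (placeholder)	-
P_t	Turn propensity (placeholder)	-
P_c	Coil propensity (placeholder)	-
Ca	Helical contact area (placeholder)	-
F	Mean rms fluctuation (placeholder)	-
Br	Buriedness (placeholder)	-
Ra	Solvent-accessible reduction ratio (placeholder)	-
Ns	Average number of surrounding residues (placeholder)	-
alpha_N	Power to be at the N-terminal of helix (placeholder)	-
alpha_C	Power to be at the C-terminal of helix (placeholder)	-
alpha_m	Power to be in the middle of helix (placeholder)	-
V0	Partial specific volume (placeholder)	-
Nm	Average medium-range contacts (placeholder)	-
Nl	Average long-range contacts (placeholder)	-
Hgm	Combined surrounding hydrophobicity (placeholder)	-
ASA_D	Solvent-accessible surface area, denatured (placeholder)	-
ASA_N	Solvent-accessible surface area, native (placeholder)	-
dASA	ASA change on unfolding (placeholder)	-
dGh	Gibbs free energy change of hydration (placeholder)	-
G_hD	Hydration free energy, denatured (placeholder)	-
G_hN	Hydration free energy, native (placeholder)	-
dHh	Enthalpy change of hydration (placeholder)	-
TdSh_neg	Hydration entropy term -T*dS_h (placeholder)	-
dCph	Unfolding hydration heat-capacity change (placeholder)	-
dGc	Chain free energy change (placeholder)	-
dHc	Chain enthalpy change (placeholder)	-
TdSc_neg	Chain entropy term -T*dS_c (placeholder)	-
dG	Unfolding Gibbs free energy change (placeholder)	-
dH	Unfolding enthalpy change (placeholder)	-
TdS_neg	Unfolding entropy term -T*dS (placeholder)	-
v	Partial volume (placeholder)	-
s	Shape factor (placeholder)	-
f	Flexibility (placeholder)	-
P_phi_psi	Backbone dihedral propensity (placeholder)	-
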