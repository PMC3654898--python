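# Published position-specific statistical potentials (kcal/mol) for
# non-amyloid (amorphous beta-aggregate forming) hexapeptides:
# 20 residues x 6 positions. Cells printed as 0.000 correspond to residues
# never observed at that position (treated as unobserved on load).
res	1	2	3	4	5	6
A	0.423	-0.070	0.622	0.927	0.622	0.757
C	0.000	0.093	-0.320	0.500	0.000	0.000
D	0.214	0.718	0.306	0.548	0.414	0.306
E	-0.073	-0.206	-0.244	-0.021	0.340	-0.874
F	-0.250	0.054	-0.772	-0.492	-0.864	-0.359
G	0.710	0.375	0.879	0.467	1.528	0.225
H	-0.165	0.139	0.382	0.139	0.382	0.382
I	0.280	0.108	0.280	-0.866	-1.122	0.038
K	-0.370	0.285	0.192	0.393	0.285	0.393
L	0.516	-0.031	0.273	-0.423	0.423	0.011
M	0.126	-0.178	0.369	0.778	0.778	-0.378
N	-0.028	1.207	-0.270	-0.099	0.251	0.385
P	0.397	0.566	0.397	0.262	0.262	0.262
Q	0.451	0.451	0.040	0.282	0.282	-0.052
R	-0.050	0.604	0.604	0.300	0.848	0.192
S	-0.827	0.132	0.132	0.303	0.716	0.061
T	0.117	-0.899	0.530	0.196	0.942	-0.125
V	0.402	0.310	-0.681	0.645	0.310	0.645
W	-0.130	0.114	-0.634	0.521	0.114	-0.130
Y	-0.240	-0.360	0.413	-0.170	-0.503	0.243
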