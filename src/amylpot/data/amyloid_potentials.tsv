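# Published position-specific statistical potentials (kcal/mol) for
# amyloid-fibril-forming hexapeptides: 20 residues x 6 positions.
# Cells printed as 0.000 correspond to residues never observed at that
# position in the source compilation (treated as unobserved on load).
res	1	2	3	4	5	6
A	0.510	0.814	1.469	1.056	0.000	0.814
C	0.000	-0.434	-0.021	-0.021	0.000	-0.263
D	0.848	0.848	1.259	0.000	0.000	0.606
E	0.639	0.335	0.135	0.468	1.294	-0.974
F	-0.060	-0.231	-0.833	-0.060	-0.806	-0.300
G	-0.007	0.596	1.422	0.000	0.000	1.009
H	-0.386	0.027	0.000	0.681	0.000	0.000
I	0.408	-0.137	1.235	-1.225	-1.460	0.580
K	0.080	0.000	0.000	1.239	0.000	0.826
L	0.310	-0.103	0.231	-0.252	1.056	0.310
M	-0.291	0.255	0.668	0.000	0.000	-0.491
N	-0.142	0.685	0.442	-0.688	0.000	0.029
P	0.000	0.000	0.000	0.000	0.000	0.000
Q	0.340	-0.314	-0.165	0.000	0.996	-0.534
R	0.734	0.000	0.000	0.000	0.000	0.000
S	-1.036	0.602	0.098	1.259	1.259	-0.171
T	0.829	-1.089	0.000	0.175	1.244	0.083
V	-0.014	-0.071	-1.191	1.355	0.000	-0.071
W	-0.413	0.000	-0.546	-0.747	0.413	0.413
Y	-0.204	-0.353	0.956	-0.283	-0.798	-0.112
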