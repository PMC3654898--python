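# Amino acid composition (percent) of globular proteins, used as the
# background for position-specific propensities.
res	percent
A	8.47
C	1.39
D	5.97
E	6.32
F	3.91
G	7.82
H	2.26
I	5.71
K	5.76
L	8.48
M	2.21
N	4.54
P	4.63
Q	3.82
R	4.93
S	5.94
T	5.79
V	7.02
W	1.44
Y	3.58
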