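residue	dg_mid	sigma
A	0.11	6.0
C	-0.13	6.0
D	3.49	6.0
E	2.68	6.0
F	-0.32	6.0
G	0.74	6.0
H	2.06	6.0
I	-0.60	6.0
K	2.71	6.0
L	-0.55	6.0
M	-0.10	6.0
N	2.05	6.0
P	2.23	6.0
Q	2.36	6.0
R	2.58	6.0
S	0.84	6.0
T	0.52	6.0
V	-0.31	6.0
W	0.30	6.0
Y	0.68	6.0
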