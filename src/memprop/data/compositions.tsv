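# Default amino-acid compositions used by the synthetic-structure generator.
# tm: lipid-facing transmembrane helix composition, strongly apolar
#     (L/I/V/F/A-rich, charged residues rare).
# em: solvent-exposed extramembrane segments, strongly polar/charged
#     (D/E/K/R/S/N-rich, aliphatics rare).
# Columns sum to 1. Editable.
aa	tm	em
A	0.110	0.035
C	0.020	0.003
D	0.0025	0.110
E	0.0025	0.120
F	0.100	0.005
G	0.050	0.070
H	0.005	0.030
I	0.150	0.010
K	0.0025	0.110
L	0.200	0.020
M	0.040	0.004
N	0.010	0.090
P	0.020	0.060
Q	0.010	0.070
R	0.0025	0.100
S	0.035	0.090
T	0.050	0.050
V	0.140	0.015
W	0.025	0.003
Y	0.025	0.005
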