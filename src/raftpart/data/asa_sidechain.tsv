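# Side-chain solvent-accessible surface areas (ASA), in Å² per residue.
# Standard-state values for residue X in an extended Gly-X-Gly context
# (the classical tripeptide reference-state side-chain areas used for
# sequence-based ASA summation). Side chain only; backbone excluded.
# Glycine has no heavy side-chain atom and is assigned 0.
# format: one-letter residue code <TAB> ASA in Å²
A	67.0
R	196.0
N	113.0
D	106.0
C	104.0
Q	144.0
E	138.0
G	0.0
H	151.0
I	140.0
L	137.0
K	167.0
M	160.0
F	175.0
P	105.0
S	80.0
T	102.0
W	217.0
Y	187.0
V	117.0
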