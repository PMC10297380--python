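# Eisenberg consensus hydrophobicity, min-max rescaled to [0,1]
ALA	0.807229
ARG	0.000000
ASN	0.449799
ASP	0.417671
CYS	0.722892
GLN	0.429719
GLU	0.457831
GLY	0.771084
HIS	0.546185
ILE	1.000000
LEU	0.919679
LYS	0.265060
MET	0.811245
PHE	0.951807
PRO	0.678715
SER	0.602410
THR	0.634538
TRP	0.855422
TYR	0.714859
VAL	0.923695
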