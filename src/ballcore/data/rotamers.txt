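# Illustrative rotamer library: RESIDUE CHI1 CHI2 CHI3 CHI4 PROBABILITY
# Blank chi values are marked '-'.  Three chi1 wells per residue; chains
# extended (180) beyond chi1.  Probabilities per residue sum to 1 and are
# listed in descending order.
ARG -60 180 180 180 0.5
ARG 180 180 180 180 0.3
ARG  60 180 180 180 0.2
ASN -60 -60 - - 0.5
ASN 180 -60 - - 0.3
ASN  60 -60 - - 0.2
ASP -60 0 - - 0.5
ASP 180 0 - - 0.3
ASP  60 0 - - 0.2
CYS -60 - - - 0.5
CYS 180 - - - 0.3
CYS  60 - - - 0.2
GLN -60 180 -60 - 0.5
GLN 180 180 -60 - 0.3
GLN  60 180 -60 - 0.2
GLU -60 180 0 - 0.5
GLU 180 180 0 - 0.3
GLU  60 180 0 - 0.2
HIS -60 90 - - 0.5
HIS 180 90 - - 0.3
HIS  60 90 - - 0.2
ILE -60 180 - - 0.6
ILE 180 180 - - 0.25
ILE  60 180 - - 0.15
LEU -60 180 - - 0.6
LEU 180  60 - - 0.25
LEU  60 180 - - 0.15
LYS -60 180 180 180 0.5
LYS 180 180 180 180 0.3
LYS  60 180 180 180 0.2
MET -60 180 180 - 0.5
MET 180 180 180 - 0.3
MET  60 180 180 - 0.2
PHE -60 90 - - 0.5
PHE 180 90 - - 0.3
PHE  60 90 - - 0.2
SER  60 - - - 0.45
SER -60 - - - 0.3
SER 180 - - - 0.25
THR  60 - - - 0.45
THR -60 - - - 0.3
THR 180 - - - 0.25
TRP -60 90 - - 0.5
TRP 180 90 - - 0.3
TRP  60 90 - - 0.2
TYR -60 90 - - 0.5
TYR 180 90 - - 0.3
TYR  60 90 - - 0.2
VAL 180 - - - 0.6
VAL -60 - - - 0.25
VAL  60 - - - 0.15
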