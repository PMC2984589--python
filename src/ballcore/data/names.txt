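# Atom-name normalization map: ALIAS CANONICAL [RESIDUE]
# Names are stripped of padding first; digit-prefixed hydrogen names
# (1HB -> HB1) are handled by a generic rotation rule in code.
HN H
HT1 H1
HT2 H2
HT3 H3
OT1 O
OT2 OXT
OCT1 O
OCT2 OXT
O1 O
O2 OXT
OW O HOH
HW1 H1 HOH
HW2 H2 HOH
HB1 HB2 PRO
SD1 SD MET
OD OD1 ASN
ND ND2 ASN
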