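# Atomic valence penalty table: ELEMENT CHARGE VALENCE PENALTY
# Zero-penalty rows list the allowed valence sums; deviation from the
# nearest allowed valence costs 32 per unit (applied in code).
H 0 1 0
C 0 4 0
N 0 3 0
N 1 4 0
N -1 2 0
O 0 2 0
O -1 1 0
P 0 3 0
P 0 5 0
S 0 2 0
S 0 4 0
S 0 6 0
B 0 3 0
F 0 1 0
Cl 0 1 0
Br 0 1 0
I 0 1 0
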