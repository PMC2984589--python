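# Minimal AMBER-functional-form parameter set covering the bundled
# amino-acid templates and water.  Self-authored values in the style of
# published protein force fields; not a redistribution of any parm release.
#
# [options]  key value
# [types]    NAME EPSILON RMIN2 MASS          (kcal/mol, Angstrom, amu)
# [stretch]  T1 T2 K R0                       (kcal/mol/A^2, A)
# [bend]     T1 T2 T3 K THETA0               (kcal/mol/rad^2, degrees; X = wildcard)
# [torsion]  T1 T2 T3 T4 VHALF N GAMMA       (kcal/mol, -, degrees; X = wildcard,
#            multiple rows with the same key add cosine terms)

[options]
form amber
scee 1.2
scnb 2.0
coulomb 332.0637
cutoff 12.0

[types]
H   0.0157 0.6000 1.008
HC  0.0157 1.4870 1.008
HO  0.0000 0.0000 1.008
HS  0.0157 0.6000 1.008
HW  0.0000 0.0000 1.008
CT  0.1094 1.9080 12.011
C   0.0860 1.9080 12.011
CA  0.0860 1.9080 12.011
N   0.1700 1.8240 14.007
N2  0.1700 1.8240 14.007
N3  0.1700 1.8240 14.007
NA  0.1700 1.8240 14.007
NB  0.1700 1.8240 14.007
O   0.2100 1.6612 15.999
O2  0.2100 1.6612 15.999
OH  0.2104 1.7210 15.999
OW  0.1520 1.7683 15.999
S   0.2500 2.0000 32.066
SH  0.2500 2.0000 32.066

[stretch]
CT CT 310.0 1.526
CT HC 340.0 1.090
CT C  317.0 1.522
C  O  570.0 1.229
C  O2 656.0 1.250
C  N  490.0 1.335
C  OH 450.0 1.364
C  N2 481.0 1.340
CT N  337.0 1.449
CT N2 337.0 1.463
CT N3 367.0 1.471
N  H  434.0 1.010
N2 H  434.0 1.010
N3 H  434.0 1.010
NA H  434.0 1.010
CT OH 320.0 1.410
OH HO 553.0 0.960
CT S  227.0 1.810
CT SH 237.0 1.810
SH HS 274.0 1.336
S  S  166.0 2.038
CT CA 317.0 1.510
CA CA 469.0 1.400
CA HC 367.0 1.080
CA NA 427.0 1.381
CA NB 414.0 1.391
CA OH 450.0 1.364
OW HW 553.0 0.960

[bend]
HW OW HW 100.0 104.5
CT CT CT 40.0 109.5
CT CT HC 50.0 109.5
HC CT HC 35.0 109.5
CT C  O  80.0 120.4
CT C  N  70.0 116.6
O  C  N  80.0 122.9
O  C  O2 80.0 126.0
O2 C  O2 80.0 126.0
C  N  CT 50.0 121.9
C  N  H  50.0 119.8
CT N  H  50.0 118.0
H  N  H  35.0 120.0
CT CT N  80.0 109.7
N  CT C  63.0 110.1
X  CT X  50.0 109.5
X  C  X  70.0 120.0
X  CA X  63.0 120.0
X  N  X  50.0 120.0
X  N2 X  50.0 120.0
X  N3 X  50.0 109.5
X  NA X  70.0 109.0
X  NB X  70.0 109.0
X  OH X  55.0 108.5
X  OW X  100.0 104.5
X  S  X  62.0 99.0
X  SH X  43.0 96.0

[torsion]
X CT CT X 0.1556 3 0.0
X CT C  X 0.0000 2 180.0
X C  N  X 2.5000 2 180.0
X CT N  X 0.0000 2 0.0
X CT N2 X 0.0000 3 0.0
X CT N3 X 0.1556 3 0.0
X CT OH X 0.1667 3 0.0
X CT S  X 0.3333 3 0.0
X CT SH X 0.2500 3 0.0
X CT CA X 0.0000 2 0.0
X CA CA X 3.6250 2 180.0
X CA NA X 1.5000 2 180.0
X CA NB X 2.4000 2 180.0
X C  N2 X 2.4000 2 180.0
X C  O2 X 1.4000 2 180.0
X C  OH X 1.1500 2 180.0
X CA OH X 0.9000 2 180.0
X S  S  X 0.6000 3 0.0
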