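symbol	lightest_isotope_mass
H	1.007825032
B	11.009305167
C	12.000000000
N	14.003074004
O	15.994914620
F	18.998403163
Na	22.989769282
Si	27.976926535
P	30.973761998
S	31.972071174
Cl	34.968852682
K	38.963706486
Br	78.918337601
I	126.904471853
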