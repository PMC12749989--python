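element	radius
H	1.20
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
F	1.47
CL	1.75
BR	1.85
I	1.98
SE	1.90
FE	2.00
ZN	1.39
MG	1.73
CA	2.31
NA	2.27
K	2.75
MN	2.00
CU	1.40
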