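parameter,min,max
BW,0.201,0.273
VLC,0.0340,0.0460
VFC,0.08585,0.11615
VSC,0.55250,0.74750
VRC,0.05185,0.07015
VBC,0.05015,0.06785
QCC,11.900,16.100
QPC,11.900,16.100
QLC,0.21250,0.28750
QFC,0.12070,0.16330
QSC,0.12750,0.17250
QRC,0.38930,0.52670
PB,27880,37720
PL,0.646,0.874
PF,0.315,0.426
PS,0.680,0.920
PR,0.646,0.874
PL2,0.646,0.874
PF2,0.111,0.150
PS2,0.680,0.920
PR2,0.646,0.874
KM,5.355,7.245
VMAX,1284.35,1737.65
KEX,0.004,0.005
KUP,3.400,4.600
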