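# Baseline physiological and chemical parameters for the rat EGME/MAA PBPK
# model.  Fractional volumes are fractions of body weight; fractional flows
# are fractions of cardiac output; see qivive.pbpk.PBPKParameters for units.
BW: 0.237
VLC: 0.040
VFC: 0.101
VSC: 0.650
VRC: 0.061
VBC: 0.059
QCC: 14.0
QPC: 14.0
QLC: 0.250
QFC: 0.142
QSC: 0.150
QRC: 0.458
PB: 32800.0
PL: 0.76
PF: 0.37
PS: 0.80
PR: 0.76
PL2: 0.76
PF2: 0.13
PS2: 0.80
PR2: 0.76
KM: 6.3
VMAX: 1511.0
KEX: 0.0045
KUP: 4.0
HEP: 110.0
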