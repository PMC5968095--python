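route,parameter,median,lo,hi
oral,BW,0.250,0.245,0.255
oral,PS2,0.746,0.662,0.835
oral,KEX,0.0041,0.0038,0.0047
inhalation,BW,0.249,0.245,0.254
inhalation,QPC,12.46,11.92,15.27
inhalation,PS2,0.724,0.527,0.900
inhalation,KEX,0.0049,0.0042,0.0052
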