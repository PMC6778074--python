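# Zr-89 (78.41 h): EC (77%) and beta+ (22.7%) to Y-89m/Y-89; the 909 keV
# gamma of the short-lived Y-89m level is folded into this record.
halflife_s	282276
mode	Y-89	1.0
beta+	902	0.227
gamma	909.15	0.9904
gamma	1713.0	0.0075
gamma	1744.5	0.0012
electron	13.0	0.12	auger
electron	1.7	1.20	auger
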