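# Cu-67 (61.83 h), beta- decay to stable Zn-67.
halflife_s	222588
mode	Zn-67	1.0
beta-	561.7	0.200
beta-	482.0	0.220
beta-	394.9	0.570
beta-	189.5	0.010
gamma	91.27	0.0700
gamma	93.31	0.1610
gamma	184.58	0.4870
gamma	300.22	0.0080
electron	175.0	0.011	conversion
electron	7.2	0.20	auger
electron	0.9	1.20	auger
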