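# Pb-211 (36.1 min), beta- decay to Bi-211. Endpoints in keV.
halflife_s	2166
mode	Bi-211	1.0
beta-	1372	0.913
beta-	967	0.015
beta-	535	0.063
gamma	404.85	0.0381
gamma	427.09	0.0181
gamma	704.64	0.0046
gamma	831.96	0.0352
electron	316.0	0.004	conversion
electron	8.0	0.03	auger
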