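# Lu-177 (6.647 d), beta- decay to stable Hf-177 with strong internal
# conversion of the 113/208 keV transitions.
halflife_s	574301
mode	Hf-177	1.0
beta-	498.3	0.794
beta-	385.3	0.091
beta-	176.5	0.122
gamma	112.95	0.0617
gamma	208.37	0.1041
gamma	249.67	0.0021
gamma	321.32	0.0022
electron	47.6	0.052	conversion
electron	103.2	0.0115	conversion
electron	143.1	0.0080	conversion
electron	6.2	0.10	auger
electron	1.0	0.70	auger
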