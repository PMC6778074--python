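# Rn-219 (3.96 s), alpha decay to Po-215. Values per decay, keV.
halflife_s	3.96
mode	Po-215	1.0
alpha	6425.0	0.075
alpha	6552.6	0.129
alpha	6819.1	0.794
gamma	271.23	0.108
gamma	401.81	0.066
electron	172.8	0.012	conversion
electron	9.0	0.06	auger
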