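# Po-211 (0.516 s), alpha decay to Pb-207.
halflife_s	0.516
mode	Pb-207	1.0
alpha	6891.5	0.0056
alpha	7450.3	0.9890
gamma	569.7	0.0054
gamma	897.8	0.0051
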