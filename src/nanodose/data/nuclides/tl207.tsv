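# Tl-207 (4.77 min), beta- decay to stable Pb-207.
halflife_s	286.2
mode	Pb-207	1.0
beta-	1418	0.997
gamma	897.8	0.0026
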