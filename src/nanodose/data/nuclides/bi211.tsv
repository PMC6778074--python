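# Bi-211 (2.14 min): alpha to Tl-207 (99.724%) with a weak beta- branch
# to Po-211 (0.276%).
halflife_s	128.4
mode	Tl-207	0.99724
mode	Po-211	0.00276
alpha	6278.2	0.161
alpha	6622.9	0.836
beta-	574	0.00276
gamma	351.03	0.1300
electron	263.0	0.011	conversion
electron	8.5	0.04	auger
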