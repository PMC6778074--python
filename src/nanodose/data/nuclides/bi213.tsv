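# Bi-213 (45.61 min): beta- to Po-213 (97.80%) and alpha to Tl-209 (2.20%);
# both branches converge on Pb-209 -> Bi-209 (treated as stable).
halflife_s	2736.6
mode	Po-213	0.9780
mode	Tl-209	0.0220
beta-	1423	0.649
beta-	983	0.309
alpha	5875	0.0194
alpha	5558	0.0018
gamma	440.45	0.2610
gamma	1100.2	0.0025
electron	347.0	0.003	conversion
electron	8.0	0.05	auger
electron	1.0	0.40	auger
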