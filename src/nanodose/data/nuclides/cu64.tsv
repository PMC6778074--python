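# Cu-64 (12.701 h): beta- (38.5%) to Zn-64 and EC/beta+ (61.5%) to Ni-64.
# beta+ intensity 17.6% per decay; the EC remainder yields Ni K/L Auger
# cascades. Annihilation photons are produced in transport, not listed here.
halflife_s	45723.6
mode	Zn-64	0.385
mode	Ni-64	0.615
beta-	579.4	0.385
beta+	653.1	0.176
gamma	1345.77	0.0048
electron	6.54	0.26	auger
electron	0.84	1.10	auger
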