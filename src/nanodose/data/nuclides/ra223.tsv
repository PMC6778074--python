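# Ra-223: alpha emitter heading a 6-member chain terminating at Pb-207.
# Compiled from standard nuclear-data evaluations (NuDat/ENSDF-derived, rounded).
# Intensities are per decay of this nuclide. Energies in keV.
# Records: halflife_s <s> | mode <daughter> <branching> | alpha <E> <I> |
#          gamma <E> <I> | beta- <endpoint> <I> | beta+ <endpoint> <I> |
#          electron <E> <I> <subtype: auger|conversion>
halflife_s	987552
mode	Rn-219	1.0
alpha	5433.6	0.0222
alpha	5539.8	0.0900
alpha	5606.7	0.2524
alpha	5715.9	0.5160
alpha	5747.0	0.0900
alpha	5871.3	0.0100
gamma	122.32	0.0124
gamma	144.27	0.0336
gamma	154.21	0.0570
gamma	269.46	0.1390
gamma	323.87	0.0393
gamma	338.28	0.0279
gamma	445.03	0.0128
electron	36.0	0.30	conversion
electron	171.1	0.10	conversion
electron	251.4	0.05	conversion
electron	9.6	0.35	auger
electron	1.2	1.00	auger
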