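# Alpha electronic stopping power in liquid water (ASTAR-like nodes)
# columns: energy_keV  stopping_keV_per_um
1.000000e+01	4.000000e+01
2.500000e+01	6.000000e+01
5.000000e+01	7.800000e+01
1.000000e+02	1.150000e+02
2.000000e+02	1.610000e+02
4.000000e+02	2.000000e+02
6.000000e+02	2.180000e+02
7.000000e+02	2.220000e+02
8.000000e+02	2.180000e+02
1.000000e+03	1.910000e+02
1.500000e+03	1.610000e+02
2.000000e+03	1.380000e+02
3.000000e+03	1.130000e+02
4.000000e+03	9.750000e+01
5.000000e+03	8.700000e+01
6.000000e+03	7.860000e+01
7.000000e+03	7.220000e+01
8.000000e+03	6.700000e+01
9.000000e+03	6.280000e+01
1.000000e+04	5.930000e+01
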