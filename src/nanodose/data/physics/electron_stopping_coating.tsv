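# Electron collisional stopping power, coating
# >=1 keV: Berger-Seltzer (Bethe) formula, I = 74.7 eV, rho = 1.2 g/cm3
# <1 keV: empirical liquid-water extension scaled by electron density
# columns: energy_eV  stopping_eV_per_nm
1.000000e+01	9.135123e+00
2.000000e+01	1.598646e+01
5.000000e+01	2.512159e+01
1.000000e+02	3.197293e+01
1.500000e+02	3.768238e+01
2.000000e+02	3.996616e+01
3.000000e+02	3.996616e+01
4.000000e+02	3.882427e+01
5.000000e+02	3.654049e+01
7.000000e+02	2.740537e+01
8.500000e+02	1.941214e+01
1.000000e+03	1.367715e+01
1.258925e+03	1.178249e+01
1.584893e+03	1.009141e+01
1.995262e+03	8.600446e+00
2.511886e+03	7.298970e+00
3.162278e+03	6.172250e+00
3.981072e+03	5.203600e+00
5.011872e+03	4.375809e+00
6.309573e+03	3.672059e+00
7.943282e+03	3.076495e+00
1.000000e+04	2.574540e+00
1.258925e+04	2.153038e+00
1.584893e+04	1.800291e+00
1.995262e+04	1.506015e+00
2.511886e+04	1.261256e+00
3.162278e+04	1.058276e+00
3.981072e+04	8.904377e-01
5.011872e+04	7.520803e-01
6.309573e+04	6.384003e-01
7.943282e+04	5.453423e-01
1.000000e+05	4.694970e-01
1.258925e+05	4.080104e-01
1.584893e+05	3.585017e-01
1.995262e+05	3.189905e-01
2.511886e+05	2.878330e-01
3.162278e+05	2.636640e-01
3.981072e+05	2.453471e-01
5.011872e+05	2.319305e-01
6.309573e+05	2.226092e-01
7.943282e+05	2.166949e-01
1.000000e+06	2.135929e-01
1.258925e+06	2.127858e-01
1.584893e+06	2.138243e-01
1.995262e+06	2.163213e-01
2.511886e+06	2.199494e-01
3.162278e+06	2.244374e-01
3.981072e+06	2.295665e-01
5.011872e+06	2.351649e-01
6.309573e+06	2.411010e-01
7.943282e+06	2.472767e-01
1.000000e+07	2.536203e-01
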