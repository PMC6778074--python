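# Electron collisional stopping power, water
# >=1 keV: Berger-Seltzer (Bethe) formula, I = 75.0 eV, rho = 1.0 g/cm3
# <1 keV: empirical liquid-water extension scaled by electron density
# columns: energy_eV  stopping_eV_per_nm
1.000000e+01	8.000000e+00
2.000000e+01	1.400000e+01
5.000000e+01	2.200000e+01
1.000000e+02	2.800000e+01
1.500000e+02	3.300000e+01
2.000000e+02	3.500000e+01
3.000000e+02	3.500000e+01
4.000000e+02	3.400000e+01
5.000000e+02	3.200000e+01
7.000000e+02	2.400000e+01
8.500000e+02	1.700000e+01
1.000000e+03	1.197764e+01
1.258925e+03	1.031957e+01
1.584893e+03	8.839308e+00
1.995262e+03	7.533971e+00
2.511886e+03	6.394348e+00
3.162278e+03	5.407620e+00
3.981072e+03	4.559230e+00
5.011872e+03	3.834141e+00
6.309573e+03	3.217655e+00
7.943282e+03	2.695902e+00
1.000000e+04	2.256128e+00
1.258925e+04	1.886821e+00
1.584893e+04	1.577740e+00
1.995262e+04	1.319881e+00
2.511886e+04	1.105401e+00
3.162278e+04	9.275261e-01
3.981072e+04	7.804421e-01
5.011872e+04	6.591898e-01
6.309573e+04	5.595615e-01
7.943282e+04	4.780043e-01
1.000000e+05	4.115314e-01
1.258925e+05	3.576419e-01
1.584893e+05	3.142498e-01
1.995262e+05	2.796198e-01
2.511886e+05	2.523114e-01
3.162278e+05	2.311283e-01
3.981072e+05	2.150746e-01
5.011872e+05	2.033162e-01
6.309573e+05	1.951475e-01
7.943282e+05	1.899653e-01
1.000000e+06	1.872483e-01
1.258925e+06	1.865431e-01
1.584893e+06	1.874557e-01
1.995262e+06	1.896470e-01
2.511886e+06	1.928299e-01
3.162278e+06	1.967666e-01
3.981072e+06	2.012654e-01
5.011872e+06	2.061756e-01
6.309573e+06	2.113819e-01
7.943282e+06	2.167983e-01
1.000000e+07	2.223618e-01
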