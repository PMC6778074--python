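# Electron collisional stopping power, iron_oxide
# >=1 keV: Berger-Seltzer (Bethe) formula, I = 286.0 eV, rho = 5.2 g/cm3
# <1 keV: empirical liquid-water extension scaled by electron density
# columns: energy_eV  stopping_eV_per_nm
1.000000e+01	1.825606e+01
2.000000e+01	3.194810e+01
5.000000e+01	5.020416e+01
1.000000e+02	6.389621e+01
1.500000e+02	7.530624e+01
2.000000e+02	7.987026e+01
3.000000e+02	7.987026e+01
4.000000e+02	7.758825e+01
5.000000e+02	7.302423e+01
7.000000e+02	5.476818e+01
8.500000e+02	3.879412e+01
1.000000e+03	2.733305e+01
1.258925e+03	2.528616e+01
1.584893e+03	2.293264e+01
1.995262e+03	2.048575e+01
2.511886e+03	1.808404e+01
3.162278e+03	1.581299e+01
3.981072e+03	1.372101e+01
5.011872e+03	1.183109e+01
6.309573e+03	1.014919e+01
7.943282e+03	8.670265e+00
1.000000e+04	7.382575e+00
1.258925e+04	6.270621e+00
1.584893e+04	5.317212e+00
1.995262e+04	4.504811e+00
2.511886e+04	3.816414e+00
3.162278e+04	3.236075e+00
3.981072e+04	2.749203e+00
5.011872e+04	2.342681e+00
6.309573e+04	2.004892e+00
7.943282e+04	1.725664e+00
1.000000e+05	1.496183e+00
1.258925e+05	1.308870e+00
1.584893e+05	1.157258e+00
1.995262e+05	1.035862e+00
2.511886e+05	9.400454e-01
3.162278e+05	8.658975e-01
3.981072e+05	8.101124e-01
5.011872e+05	7.698803e-01
6.309573e+05	7.427892e-01
7.943282e+05	7.267439e-01
1.000000e+06	7.199049e-01
1.258925e+06	7.206469e-01
1.584893e+06	7.275362e-01
1.995262e+06	7.393215e-01
2.511886e+06	7.549303e-01
3.162278e+06	7.734648e-01
3.981072e+06	7.941940e-01
5.011872e+06	8.165388e-01
6.309573e+06	8.400526e-01
7.943282e+06	8.643999e-01
1.000000e+07	8.893338e-01
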