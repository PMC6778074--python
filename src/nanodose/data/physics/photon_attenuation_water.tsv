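# Photon mass attenuation coefficients, water (coherent, pair production ignored)
# incoherent: Klein-Nishina per electron; photoelectric: Z^4.5/E^3
# parametrization calibrated to water at 10 keV; Fe K-edge jump 8.2
# columns: energy_keV  total_cm2_g  photoelectric_cm2_g  incoherent_cm2_g
1.000000e+00	4.940222e+03	4.940000e+03	2.215143e-01
1.122018e+00	3.497474e+03	3.497252e+03	2.214092e-01
1.258925e+00	2.476086e+03	2.475865e+03	2.212915e-01
1.412538e+00	1.752999e+03	1.752778e+03	2.211596e-01
1.584893e+00	1.241093e+03	1.240872e+03	2.210118e-01
1.778279e+00	8.786909e+02	8.784700e+02	2.208463e-01
1.995262e+00	6.221298e+02	6.219092e+02	2.206611e-01
2.238721e+00	4.404984e+02	4.402780e+02	2.204537e-01
2.511886e+00	3.119131e+02	3.116929e+02	2.202216e-01
2.818383e+00	2.208817e+02	2.206617e+02	2.199619e-01
3.162278e+00	1.564362e+02	1.562165e+02	2.196715e-01
3.548134e+00	1.108122e+02	1.105928e+02	2.193468e-01
3.981072e+00	7.851271e+01	7.829372e+01	2.189840e-01
4.466836e+00	5.564629e+01	5.542771e+01	2.185788e-01
5.011872e+00	3.945794e+01	3.923981e+01	2.181265e-01
5.623413e+00	2.799728e+01	2.777966e+01	2.176220e-01
6.309573e+00	1.988355e+01	1.966649e+01	2.170594e-01
7.079458e+00	1.413924e+01	1.392281e+01	2.164328e-01
7.943282e+00	1.007233e+01	9.856596e+00	2.157353e-01
8.912509e+00	7.192895e+00	6.977935e+00	2.149597e-01
1.000000e+01	5.154098e+00	4.940000e+00	2.140982e-01
1.122018e+01	3.710394e+00	3.497252e+00	2.131423e-01
1.258925e+01	2.687948e+00	2.475865e+00	2.120830e-01
1.412538e+01	1.963689e+00	1.752778e+00	2.109110e-01
1.584893e+01	1.450488e+00	1.240872e+00	2.096161e-01
1.778279e+01	1.086658e+00	8.784700e-01	2.081882e-01
1.995262e+01	8.285256e-01	6.219092e-01	2.066164e-01
2.238721e+01	6.451680e-01	4.402780e-01	2.048900e-01
2.511886e+01	5.146912e-01	3.116929e-01	2.029983e-01
2.818383e+01	4.215924e-01	2.206617e-01	2.009307e-01
3.162278e+01	3.548936e-01	1.562165e-01	1.986770e-01
3.548134e+01	3.068210e-01	1.105928e-01	1.962282e-01
3.981072e+01	2.718697e-01	7.829372e-02	1.935760e-01
4.466836e+01	2.461414e-01	5.542771e-02	1.907137e-01
5.011872e+01	2.268763e-01	3.923981e-02	1.876365e-01
5.623413e+01	2.121216e-01	2.777966e-02	1.843420e-01
6.309573e+01	2.004966e-01	1.966649e-02	1.808301e-01
7.079458e+01	1.910266e-01	1.392281e-02	1.771038e-01
7.943282e+01	1.830260e-01	9.856596e-03	1.731694e-01
8.912509e+01	1.760142e-01	6.977935e-03	1.690363e-01
1.000000e+02	1.696573e-01	4.940000e-03	1.647173e-01
1.122018e+02	1.637260e-01	3.497252e-03	1.602287e-01
1.258925e+02	1.580654e-01	2.475865e-03	1.555895e-01
1.412538e+02	1.525740e-01	1.752778e-03	1.508213e-01
1.584893e+02	1.471885e-01	1.240872e-03	1.459476e-01
1.778279e+02	1.418718e-01	8.784700e-04	1.409933e-01
1.995262e+02	1.366056e-01	6.219092e-04	1.359837e-01
2.238721e+02	1.313840e-01	4.402780e-04	1.309437e-01
2.511886e+02	1.262091e-01	3.116929e-04	1.258974e-01
2.818383e+02	1.210877e-01	2.206617e-04	1.208670e-01
3.162278e+02	1.160289e-01	1.562165e-04	1.158727e-01
3.548134e+02	1.110425e-01	1.105928e-04	1.109319e-01
3.981072e+02	1.061379e-01	7.829372e-05	1.060596e-01
4.466836e+02	1.013236e-01	5.542771e-05	1.012682e-01
5.011872e+02	9.660670e-02	3.923981e-05	9.656746e-02
5.623413e+02	9.199301e-02	2.777966e-05	9.196523e-02
6.309573e+02	8.748719e-02	1.966649e-05	8.746752e-02
7.079458e+02	8.309294e-02	1.392281e-05	8.307902e-02
7.943282e+02	7.881331e-02	9.856596e-06	7.880345e-02
8.912509e+02	7.465089e-02	6.977935e-06	7.464392e-02
1.000000e+03	7.060810e-02	4.940000e-06	7.060316e-02
1.122018e+03	6.668724e-02	3.497252e-06	6.668374e-02
1.258925e+03	6.289062e-02	2.475865e-06	6.288815e-02
1.412538e+03	5.922057e-02	1.752778e-06	5.921882e-02
1.584893e+03	5.567937e-02	1.240872e-06	5.567813e-02
1.778279e+03	5.226920e-02	8.784700e-07	5.226832e-02
1.995262e+03	4.899201e-02	6.219092e-07	4.899139e-02
2.238721e+03	4.584946e-02	4.402780e-07	4.584902e-02
2.511886e+03	4.284279e-02	3.116929e-07	4.284248e-02
2.818383e+03	3.997275e-02	2.206617e-07	3.997253e-02
3.162278e+03	3.723950e-02	1.562165e-07	3.723935e-02
3.548134e+03	3.464262e-02	1.105928e-07	3.464251e-02
3.981072e+03	3.218106e-02	7.829372e-08	3.218098e-02
4.466836e+03	2.985313e-02	5.542771e-08	2.985308e-02
5.011872e+03	2.765656e-02	3.923981e-08	2.765652e-02
5.623413e+03	2.558850e-02	2.777966e-08	2.558847e-02
6.309573e+03	2.364561e-02	1.966649e-08	2.364559e-02
7.079458e+03	2.182410e-02	1.392281e-08	2.182409e-02
7.943282e+03	2.011979e-02	9.856596e-09	2.011978e-02
8.912509e+03	1.852818e-02	6.977935e-09	1.852817e-02
1.000000e+04	1.704455e-02	4.940000e-09	1.704455e-02
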