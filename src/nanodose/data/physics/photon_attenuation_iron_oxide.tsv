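# Photon mass attenuation coefficients, iron_oxide (coherent, pair production ignored)
# incoherent: Klein-Nishina per electron; photoelectric: Z^4.5/E^3
# parametrization calibrated to water at 10 keV; Fe K-edge jump 8.2
# columns: energy_keV  total_cm2_g  photoelectric_cm2_g  incoherent_cm2_g
1.000000e+00	2.905514e+04	2.905495e+04	1.899050e-01
1.122018e+00	2.056952e+04	2.056933e+04	1.898149e-01
1.258925e+00	1.456216e+04	1.456197e+04	1.897140e-01
1.412538e+00	1.030927e+04	1.030908e+04	1.896009e-01
1.584893e+00	7.298463e+03	7.298273e+03	1.894743e-01
1.778279e+00	5.166971e+03	5.166782e+03	1.893324e-01
1.995262e+00	3.657991e+03	3.657801e+03	1.891735e-01
2.238721e+00	2.589714e+03	2.589525e+03	1.889957e-01
2.511886e+00	1.833432e+03	1.833243e+03	1.887967e-01
2.818383e+00	1.298025e+03	1.297837e+03	1.885741e-01
3.162278e+00	9.189865e+02	9.187982e+02	1.883252e-01
3.548134e+00	6.506473e+02	6.504593e+02	1.880468e-01
3.981072e+00	4.606776e+02	4.604899e+02	1.877358e-01
4.466836e+00	3.261893e+02	3.260019e+02	1.873885e-01
5.011872e+00	2.309787e+02	2.307917e+02	1.870007e-01
5.623413e+00	1.635746e+02	1.633880e+02	1.865681e-01
6.309573e+00	1.158559e+02	1.156698e+02	1.860859e-01
7.079458e+00	8.207352e+01	8.188797e+01	1.855486e-01
7.104888e+00	8.119735e+01	8.101182e+01	1.855310e-01
7.119112e+00	6.273145e+02	6.271289e+02	1.855211e-01
7.943282e+00	4.516606e+02	4.514756e+02	1.849507e-01
8.912509e+00	3.198046e+02	3.196203e+02	1.842858e-01
1.000000e+01	2.264574e+02	2.262738e+02	1.835472e-01
1.122018e+01	1.603723e+02	1.601896e+02	1.827277e-01
1.258925e+01	1.135874e+02	1.134056e+02	1.818196e-01
1.412538e+01	8.046580e+01	8.028498e+01	1.808148e-01
1.584893e+01	5.701712e+01	5.683742e+01	1.797047e-01
1.778279e+01	4.041629e+01	4.023781e+01	1.784805e-01
1.995262e+01	2.866332e+01	2.848619e+01	1.771330e-01
2.238721e+01	2.034233e+01	2.016668e+01	1.756530e-01
2.511886e+01	1.445094e+01	1.427691e+01	1.740312e-01
2.818383e+01	1.027954e+01	1.010728e+01	1.722586e-01
3.162278e+01	7.325733e+00	7.155407e+00	1.703266e-01
3.548134e+01	5.233867e+00	5.065640e+00	1.682272e-01
3.981072e+01	3.752152e+00	3.586199e+00	1.659534e-01
4.466836e+01	2.702334e+00	2.538834e+00	1.634995e-01
5.011872e+01	1.958218e+00	1.797357e+00	1.608615e-01
5.623413e+01	1.430468e+00	1.272431e+00	1.580371e-01
6.309573e+01	1.055839e+00	9.008123e-01	1.550263e-01
7.079458e+01	7.895581e-01	6.377263e-01	1.518318e-01
7.943282e+01	5.999344e-01	4.514756e-01	1.484588e-01
8.912509e+01	4.645357e-01	3.196203e-01	1.449154e-01
1.000000e+02	3.674866e-01	2.262738e-01	1.412128e-01
1.122018e+02	2.975543e-01	1.601896e-01	1.373647e-01
1.258925e+02	2.467930e-01	1.134056e-01	1.333874e-01
1.412538e+02	2.095846e-01	8.028498e-02	1.292996e-01
1.584893e+02	1.819588e-01	5.683742e-02	1.251214e-01
1.778279e+02	1.611119e-01	4.023781e-02	1.208741e-01
1.995262e+02	1.450655e-01	2.848619e-02	1.165793e-01
2.238721e+02	1.324252e-01	2.016668e-02	1.122586e-01
2.511886e+02	1.222093e-01	1.427691e-02	1.079323e-01
2.818383e+02	1.137270e-01	1.010728e-02	1.036198e-01
3.162278e+02	1.064935e-01	7.155407e-03	9.933806e-02
3.548134e+02	1.001679e-01	5.065640e-03	9.510231e-02
3.981072e+02	9.451149e-02	3.586199e-03	9.092529e-02
4.466836e+02	8.935641e-02	2.538834e-03	8.681758e-02
5.011872e+02	8.458499e-02	1.797357e-03	8.278764e-02
5.623413e+02	8.011456e-02	1.272431e-03	7.884213e-02
6.309573e+02	7.588704e-02	9.008123e-04	7.498623e-02
7.079458e+02	7.186168e-02	6.377263e-04	7.122395e-02
7.943282e+02	6.800996e-02	4.514756e-04	6.755849e-02
8.912509e+02	6.431212e-02	3.196203e-04	6.399250e-02
1.000000e+03	6.075462e-02	2.262738e-04	6.052835e-02
1.122018e+03	5.732841e-02	1.601896e-04	5.716822e-02
1.258925e+03	5.402765e-02	1.134056e-04	5.391424e-02
1.412538e+03	5.084880e-02	8.028498e-05	5.076851e-02
1.584893e+03	4.778991e-02	5.683742e-05	4.773307e-02
1.778279e+03	4.485006e-02	4.023781e-05	4.480982e-02
1.995262e+03	4.202898e-02	2.848619e-05	4.200050e-02
2.238721e+03	3.932670e-02	2.016668e-05	3.930654e-02
2.511886e+03	3.674330e-02	1.427691e-05	3.672902e-02
2.818383e+03	3.427870e-02	1.010728e-05	3.426860e-02
3.162278e+03	3.193258e-02	7.155407e-06	3.192543e-02
3.548134e+03	2.970422e-02	5.065640e-06	2.969916e-02
3.981072e+03	2.759246e-02	3.586199e-06	2.758887e-02
4.466836e+03	2.559569e-02	2.538834e-06	2.559315e-02
5.011872e+03	2.371183e-02	1.797357e-06	2.371004e-02
5.623413e+03	2.193836e-02	1.272431e-06	2.193709e-02
6.309573e+03	2.027236e-02	9.008123e-07	2.027146e-02
7.079458e+03	1.871051e-02	6.377263e-07	1.870987e-02
7.943282e+03	1.724921e-02	4.514756e-07	1.724876e-02
8.912509e+03	1.588459e-02	3.196203e-07	1.588427e-02
1.000000e+04	1.461258e-02	2.262738e-07	1.461236e-02
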