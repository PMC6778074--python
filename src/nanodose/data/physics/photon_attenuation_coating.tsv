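# Photon mass attenuation coefficients, coating (coherent, pair production ignored)
# incoherent: Klein-Nishina per electron; photoelectric: Z^4.5/E^3
# parametrization calibrated to water at 10 keV; Fe K-edge jump 8.2
# columns: energy_keV  total_cm2_g  photoelectric_cm2_g  incoherent_cm2_g
1.000000e+00	4.036663e+03	4.036452e+03	2.104799e-01
1.122018e+00	2.857800e+03	2.857589e+03	2.103800e-01
1.258925e+00	2.023229e+03	2.023018e+03	2.102682e-01
1.412538e+00	1.432398e+03	1.432187e+03	2.101428e-01
1.584893e+00	1.014121e+03	1.013911e+03	2.100024e-01
1.778279e+00	7.180039e+02	7.177940e+02	2.098452e-01
1.995262e+00	5.083689e+02	5.081593e+02	2.096692e-01
2.238721e+00	3.599587e+02	3.597492e+02	2.094721e-01
2.511886e+00	2.548922e+02	2.546829e+02	2.092515e-01
2.818383e+00	1.805107e+02	1.803017e+02	2.090048e-01
3.162278e+00	1.278526e+02	1.276438e+02	2.087289e-01
3.548134e+00	9.057333e+01	9.036491e+01	2.084204e-01
3.981072e+00	6.418154e+01	6.397346e+01	2.080757e-01
4.466836e+00	4.549743e+01	4.528974e+01	2.076907e-01
5.011872e+00	3.226994e+01	3.206268e+01	2.072609e-01
5.623413e+00	2.290542e+01	2.269864e+01	2.067815e-01
6.309573e+00	1.627565e+01	1.606941e+01	2.062470e-01
7.079458e+00	1.158192e+01	1.137627e+01	2.056515e-01
7.943282e+00	8.258770e+00	8.053781e+00	2.049888e-01
8.912509e+00	5.905892e+00	5.701641e+00	2.042518e-01
1.000000e+01	4.239886e+00	4.036452e+00	2.034332e-01
1.122018e+01	3.060114e+00	2.857589e+00	2.025249e-01
1.258925e+01	2.224537e+00	2.023018e+00	2.015184e-01
1.412538e+01	1.632592e+00	1.432187e+00	2.004048e-01
1.584893e+01	1.213085e+00	1.013911e+00	1.991744e-01
1.778279e+01	9.156116e-01	7.177940e-01	1.978176e-01
1.995262e+01	7.044834e-01	5.081593e-01	1.963241e-01
2.238721e+01	5.544329e-01	3.597492e-01	1.946837e-01
2.511886e+01	4.475692e-01	2.546829e-01	1.928863e-01
2.818383e+01	3.712233e-01	1.803017e-01	1.909216e-01
3.162278e+01	3.164241e-01	1.276438e-01	1.887802e-01
3.548134e+01	2.768183e-01	9.036491e-02	1.864534e-01
3.981072e+01	2.479067e-01	6.397346e-02	1.839333e-01
4.466836e+01	2.265033e-01	4.528974e-02	1.812135e-01
5.011872e+01	2.103524e-01	3.206268e-02	1.782897e-01
5.623413e+01	1.978579e-01	2.269864e-02	1.751593e-01
6.309573e+01	1.878917e-01	1.606941e-02	1.718223e-01
7.079458e+01	1.796579e-01	1.137627e-02	1.682817e-01
7.943282e+01	1.725970e-01	8.053781e-03	1.645432e-01
8.912509e+01	1.663176e-01	5.701641e-03	1.606160e-01
1.000000e+02	1.605486e-01	4.036452e-03	1.565122e-01
1.122018e+02	1.551047e-01	2.857589e-03	1.522472e-01
1.258925e+02	1.498620e-01	2.023018e-03	1.478390e-01
1.412538e+02	1.447405e-01	1.432187e-03	1.433083e-01
1.584893e+02	1.396913e-01	1.013911e-03	1.386774e-01
1.778279e+02	1.346877e-01	7.177940e-04	1.339699e-01
1.995262e+02	1.297180e-01	5.081593e-04	1.292099e-01
2.238721e+02	1.247807e-01	3.597492e-04	1.244210e-01
2.511886e+02	1.198807e-01	2.546829e-04	1.196260e-01
2.818383e+02	1.150265e-01	1.803017e-04	1.148462e-01
3.162278e+02	1.102283e-01	1.276438e-04	1.101006e-01
3.548134e+02	1.054963e-01	9.036491e-05	1.054060e-01
3.981072e+02	1.008404e-01	6.397346e-05	1.007764e-01
4.466836e+02	9.626894e-02	4.528974e-05	9.622365e-02
5.011872e+02	9.178915e-02	3.206268e-05	9.175709e-02
5.623413e+02	8.740682e-02	2.269864e-05	8.738412e-02
6.309573e+02	8.312653e-02	1.606941e-05	8.311046e-02
7.079458e+02	7.895194e-02	1.137627e-05	7.894056e-02
7.943282e+02	7.488603e-02	8.053781e-06	7.487797e-02
8.912509e+02	7.093134e-02	5.701641e-06	7.092564e-02
1.000000e+03	6.709020e-02	4.036452e-06	6.708617e-02
1.122018e+03	6.336485e-02	2.857589e-06	6.336199e-02
1.258925e+03	5.975749e-02	2.023018e-06	5.975547e-02
1.412538e+03	5.627036e-02	1.432187e-06	5.626892e-02
1.584893e+03	5.290562e-02	1.013911e-06	5.290461e-02
1.778279e+03	4.966537e-02	7.177940e-07	4.966465e-02
1.995262e+03	4.655146e-02	5.081593e-07	4.655095e-02
2.238721e+03	4.356548e-02	3.597492e-07	4.356512e-02
2.511886e+03	4.070860e-02	2.546829e-07	4.070835e-02
2.818383e+03	3.798154e-02	1.803017e-07	3.798136e-02
3.162278e+03	3.538445e-02	1.276438e-07	3.538432e-02
3.548134e+03	3.291694e-02	9.036491e-08	3.291685e-02
3.981072e+03	3.057800e-02	6.397346e-08	3.057793e-02
4.466836e+03	2.836603e-02	4.528974e-08	2.836599e-02
5.011872e+03	2.627888e-02	3.206268e-08	2.627885e-02
5.623413e+03	2.431384e-02	2.269864e-08	2.431382e-02
6.309573e+03	2.246774e-02	1.606941e-08	2.246772e-02
7.079458e+03	2.073696e-02	1.137627e-08	2.073695e-02
7.943282e+03	1.911755e-02	8.053781e-09	1.911754e-02
8.912509e+03	1.760523e-02	5.701641e-09	1.760522e-02
1.000000e+04	1.619550e-02	4.036452e-09	1.619550e-02
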