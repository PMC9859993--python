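# Dry air mass energy-absorption and energy-transfer coefficients.
# mu_tr = mu_en / (1 - g), g approximate radiative fraction.
# E_MeV  muen_over_rho_cm2_g  mutr_over_rho_cm2_g
1.000000e-02  4.742000e+00  4.742005e+00
1.104109e-02  3.478742e+00  3.478746e+00
1.219056e-02  2.552013e+00  2.552017e+00
1.345971e-02  1.872163e+00  1.872166e+00
1.486098e-02  1.373423e+00  1.373426e+00
1.500000e-02  1.334000e+00  1.334004e+00
1.640815e-02  1.005490e+00  1.005493e+00
1.811638e-02  7.359680e-01  7.359712e-01
2.000000e-02  5.389000e-01  5.389030e-01
2.000245e-02  5.386954e-01  5.386984e-01
2.208489e-02  3.965176e-01  3.965205e-01
2.438412e-02  2.918648e-01  2.918675e-01
2.692272e-02  2.148330e-01  2.148355e-01
2.972562e-02  1.581322e-01  1.581345e-01
3.000000e-02  1.537000e-01  1.537023e-01
3.282032e-02  1.193207e-01  1.193230e-01
3.623720e-02  9.026377e-02  9.026596e-02
4.000000e-02  6.833000e-02  6.833212e-02
4.000982e-02  6.829159e-02  6.829370e-02
4.417520e-02  5.442754e-02  5.442969e-02
4.877423e-02  4.337806e-02  4.338026e-02
5.000000e-02  4.098000e-02  4.098221e-02
5.385205e-02  3.629392e-02  3.629627e-02
5.945853e-02  3.086443e-02  3.086698e-02
6.000000e-02  3.041000e-02  3.041257e-02
6.564869e-02  2.826568e-02  2.826867e-02
7.248330e-02  2.607971e-02  2.608324e-02
8.000000e-02  2.407000e-02  2.407416e-02
8.002946e-02  2.406862e-02  2.407278e-02
8.836123e-02  2.370119e-02  2.370643e-02
9.756042e-02  2.333937e-02  2.334596e-02
1.000000e-01  2.325000e-02  2.325698e-02
1.077173e-01  2.355450e-02  2.356218e-02
1.189317e-01  2.396638e-02  2.397510e-02
1.313135e-01  2.438546e-02  2.439537e-02
1.449844e-01  2.481186e-02  2.482312e-02
1.500000e-01  2.496000e-02  2.497177e-02
1.600786e-01  2.534742e-02  2.536026e-02
1.767442e-01  2.594903e-02  2.596371e-02
1.951448e-01  2.656492e-02  2.658171e-02
2.000000e-01  2.672000e-02  2.673735e-02
2.154611e-01  2.707656e-02  2.709566e-02
2.378925e-01  2.755818e-02  2.757989e-02
2.626592e-01  2.804836e-02  2.807304e-02
2.900044e-01  2.854727e-02  2.857532e-02
3.000000e-01  2.872000e-02  2.874930e-02
3.201964e-01  2.889260e-02  2.892430e-02
3.535317e-01  2.915697e-02  2.919269e-02
3.903375e-01  2.942376e-02  2.946401e-02
4.000000e-01  2.949000e-02  2.953146e-02
4.309751e-01  2.954671e-02  2.959186e-02
4.758434e-01  2.962219e-02  2.967274e-02
5.000000e-01  2.966000e-02  2.971348e-02
5.253829e-01  2.962463e-02  2.968110e-02
5.800799e-01  2.955403e-02  2.961695e-02
6.000000e-01  2.953000e-02  2.959529e-02
6.404714e-01  2.936738e-02  2.943722e-02
7.071502e-01  2.912236e-02  2.919973e-02
7.807708e-01  2.887938e-02  2.896509e-02
8.000000e-01  2.882000e-02  2.890790e-02
8.620559e-01  2.850523e-02  2.859975e-02
9.518036e-01  2.809325e-02  2.819732e-02
1.000000e+00  2.789000e-02  2.799920e-02
1.050895e+00  2.761155e-02  2.772569e-02
1.160302e+00  2.706430e-02  2.718898e-02
1.250000e+00  2.666000e-02  2.679326e-02
1.281100e+00  2.649641e-02  2.663246e-02
1.414474e+00  2.584726e-02  2.599519e-02
1.500000e+00  2.547000e-02  2.562546e-02
1.561733e+00  2.517665e-02  2.533727e-02
1.724323e+00  2.447055e-02  2.464457e-02
1.903841e+00  2.378425e-02  2.397282e-02
2.000000e+00  2.345000e-02  2.364626e-02
2.102048e+00  2.307588e-02  2.327925e-02
2.320889e+00  2.234898e-02  2.256730e-02
2.562515e+00  2.164499e-02  2.187937e-02
2.829295e+00  2.096317e-02  2.121483e-02
3.000000e+00  2.057000e-02  2.083249e-02
3.123850e+00  2.029615e-02  2.056598e-02
3.449070e+00  1.964100e-02  1.992971e-02
3.808149e+00  1.900700e-02  1.931595e-02
4.000000e+00  1.870000e-02  1.901953e-02
4.204611e+00  1.840118e-02  1.873162e-02
4.642348e+00  1.782203e-02  1.817528e-02
5.000000e+00  1.740000e-02  1.777142e-02
5.125658e+00  1.727037e-02  1.764811e-02
5.659284e+00  1.676266e-02  1.716677e-02
6.000000e+00  1.647000e-02  1.689058e-02
6.248466e+00  1.629218e-02  1.672438e-02
6.898987e+00  1.586619e-02  1.632818e-02
7.617233e+00  1.545134e-02  1.594530e-02
8.000000e+00  1.525000e-02  1.576064e-02
8.410254e+00  1.507861e-02  1.560631e-02
9.285836e+00  1.474486e-02  1.530815e-02
1.000000e+01  1.450000e-02  1.509159e-02
1.025257e+01  1.443837e-02  1.503966e-02
1.131996e+01  1.419624e-02  1.483772e-02
1.249847e+01  1.395816e-02  1.464274e-02
1.379967e+01  1.372408e-02  1.445487e-02
1.500000e+01  1.353000e-02  1.430233e-02
1.523634e+01  1.350684e-02  1.428698e-02
1.682257e+01  1.336100e-02  1.419273e-02
1.857395e+01  1.321673e-02  1.410375e-02
2.000000e+01  1.311000e-02  1.404091e-02
2.050766e+01  1.307062e-02  1.401561e-02
2.264269e+01  1.291620e-02  1.391912e-02
2.500000e+01  1.276361e-02  1.382840e-02
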