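energy_MeV,weight
4.500000e-02,1.445511e-05
5.500000e-02,1.880804e-03
6.500000e-02,2.078442e-03
7.500000e-02,3.939064e-04
8.500000e-02,3.904157e-06
9.500000e-02,3.783459e-05
1.050000e-01,2.765522e-05
1.150000e-01,5.285845e-04
1.250000e-01,7.347180e-04
1.350000e-01,2.590102e-03
1.450000e-01,2.666705e-02
1.550000e-01,2.558352e-02
1.650000e-01,2.789323e-02
1.750000e-01,3.147067e-02
1.850000e-01,3.319080e-02
1.950000e-01,3.252052e-02
2.050000e-01,3.210167e-02
2.150000e-01,3.210500e-02
2.250000e-01,3.346681e-02
2.350000e-01,3.533614e-02
2.450000e-01,3.781231e-02
2.550000e-01,4.057702e-02
2.650000e-01,4.422634e-02
2.750000e-01,4.764527e-02
2.850000e-01,5.140285e-02
2.950000e-01,5.195588e-02
3.050000e-01,4.789701e-02
3.150000e-01,3.173405e-02
3.250000e-01,1.205317e-02
3.350000e-01,1.267667e-02
3.450000e-01,1.322000e-02
3.550000e-01,1.383017e-02
3.650000e-01,1.470771e-02
3.750000e-01,1.513155e-02
3.850000e-01,1.577622e-02
3.950000e-01,1.675992e-02
4.050000e-01,1.714293e-02
4.150000e-01,1.830309e-02
4.250000e-01,1.914748e-02
4.350000e-01,1.978391e-02
4.450000e-01,2.067893e-02
4.550000e-01,2.150404e-02
4.650000e-01,2.013223e-02
4.750000e-01,5.659851e-03
4.850000e-01,5.212060e-03
4.950000e-01,4.560823e-03
5.050000e-01,4.929294e-03
5.150000e-01,4.907450e-03
5.250000e-01,5.218198e-03
5.350000e-01,5.409860e-03
5.450000e-01,5.686857e-03
5.550000e-01,5.645911e-03
5.650000e-01,5.897325e-03
5.750000e-01,5.995302e-03
5.850000e-01,6.044587e-03
5.950000e-01,4.778287e-03
6.050000e-01,3.482820e-03
6.150000e-01,6.643899e-04
6.250000e-01,8.545014e-05
6.350000e-01,6.631699e-05
6.450000e-01,8.932526e-05
6.550000e-01,7.462633e-05
6.650000e-01,9.598471e-05
6.750000e-01,1.101829e-04
6.850000e-01,9.885954e-05
6.950000e-01,1.067825e-04
7.050000e-01,8.562196e-05
7.150000e-01,9.368709e-05
7.250000e-01,8.392939e-05
7.350000e-01,1.073788e-04
7.450000e-01,8.480772e-05
7.550000e-01,1.074803e-04
7.650000e-01,1.059882e-04
7.750000e-01,9.858529e-05
7.850000e-01,1.014167e-04
7.950000e-01,1.222127e-04
8.050000e-01,1.191863e-04
8.150000e-01,1.005412e-04
8.250000e-01,1.080819e-04
8.350000e-01,8.873851e-05
8.450000e-01,1.315075e-04
8.550000e-01,1.071029e-04
8.650000e-01,1.215130e-04
8.750000e-01,1.162334e-04
8.850000e-01,9.223225e-05
8.950000e-01,2.886688e-05
9.050000e-01,1.371878e-05
9.150000e-01,3.126818e-05
9.250000e-01,2.809659e-05
9.350000e-01,2.660383e-05
9.450000e-01,2.869351e-05
9.550000e-01,1.808983e-05
9.650000e-01,2.566565e-05
9.750000e-01,7.403531e-06
9.850000e-01,2.429865e-05
9.950000e-01,2.455689e-05
1.005000e+00,2.289707e-05
1.015000e+00,2.700367e-05
1.025000e+00,2.528394e-05
1.035000e+00,1.572680e-05
1.045000e+00,1.982192e-05
1.055000e+00,3.002876e-05
1.065000e+00,1.210150e-05
1.075000e+00,4.094971e-06
1.085000e+00,2.068762e-06
1.125000e+00,2.144456e-06
1.145000e+00,2.170517e-06
1.185000e+00,4.514045e-06
1.205000e+00,2.296836e-06
1.215000e+00,6.920150e-06
1.225000e+00,2.333048e-06
1.235000e+00,2.350881e-06
1.255000e+00,2.389490e-06
1.265000e+00,4.796057e-06
1.275000e+00,2.413013e-06
1.285000e+00,7.316663e-06
1.305000e+00,4.952990e-06
1.315000e+00,2.493356e-06
1.325000e+00,2.506353e-06
1.335000e+00,7.615287e-06
1.355000e+00,5.148469e-06
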