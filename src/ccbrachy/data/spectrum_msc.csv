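energy_MeV,weight
1.500000e-02,1.131517e-07
2.500000e-02,3.795340e-04
3.500000e-02,5.291010e-03
4.500000e-02,1.443853e-02
5.500000e-02,2.214502e-02
6.500000e-02,2.767229e-02
7.500000e-02,3.200870e-02
8.500000e-02,3.499780e-02
9.500000e-02,3.802682e-02
1.050000e-01,4.022274e-02
1.150000e-01,4.118093e-02
1.250000e-01,4.226840e-02
1.350000e-01,4.445108e-02
1.450000e-01,4.411828e-02
1.550000e-01,4.190881e-02
1.650000e-01,4.050555e-02
1.750000e-01,3.806599e-02
1.850000e-01,3.565706e-02
1.950000e-01,3.333776e-02
2.050000e-01,3.123421e-02
2.150000e-01,2.987096e-02
2.250000e-01,2.842673e-02
2.350000e-01,2.708465e-02
2.450000e-01,2.575980e-02
2.550000e-01,2.429018e-02
2.650000e-01,2.251781e-02
2.750000e-01,2.083736e-02
2.850000e-01,1.876606e-02
2.950000e-01,1.663406e-02
3.050000e-01,1.430086e-02
3.150000e-01,1.264809e-02
3.250000e-01,1.179695e-02
3.350000e-01,1.156042e-02
3.450000e-01,1.116955e-02
3.550000e-01,1.075448e-02
3.650000e-01,1.030763e-02
3.750000e-01,9.893919e-03
3.850000e-01,9.426685e-03
3.950000e-01,8.801788e-03
4.050000e-01,8.147537e-03
4.150000e-01,7.672331e-03
4.250000e-01,6.942097e-03
4.350000e-01,6.012366e-03
4.450000e-01,5.236967e-03
4.550000e-01,4.391587e-03
4.650000e-01,3.536010e-03
4.750000e-01,2.946020e-03
4.850000e-01,2.738447e-03
4.950000e-01,2.553417e-03
5.050000e-01,2.469061e-03
5.150000e-01,2.203372e-03
5.250000e-01,2.030757e-03
5.350000e-01,1.846373e-03
5.450000e-01,1.600359e-03
5.550000e-01,1.450715e-03
5.650000e-01,1.115462e-03
5.750000e-01,8.925493e-04
5.850000e-01,6.702778e-04
5.950000e-01,4.151511e-04
6.050000e-01,2.378517e-04
6.150000e-01,1.243110e-04
6.250000e-01,9.248836e-05
6.350000e-01,1.067742e-04
6.450000e-01,9.778549e-05
6.550000e-01,9.117560e-05
6.650000e-01,9.119094e-05
6.750000e-01,7.974484e-05
6.850000e-01,1.003363e-04
6.950000e-01,7.268832e-05
7.050000e-01,8.285462e-05
7.150000e-01,8.235550e-05
7.250000e-01,8.180360e-05
7.350000e-01,8.329758e-05
7.450000e-01,7.079343e-05
7.550000e-01,7.226202e-05
7.650000e-01,7.121119e-05
7.750000e-01,6.251888e-05
7.850000e-01,5.605635e-05
7.950000e-01,4.797761e-05
8.050000e-01,6.079508e-05
8.150000e-01,4.986265e-05
8.250000e-01,5.343730e-05
8.350000e-01,4.598606e-05
8.450000e-01,4.828088e-05
8.550000e-01,2.595824e-05
8.650000e-01,2.356701e-05
8.750000e-01,2.242640e-05
8.850000e-01,2.280003e-05
8.950000e-01,6.180407e-06
9.050000e-01,1.255755e-05
9.150000e-01,1.115222e-05
9.250000e-01,1.137266e-05
9.350000e-01,1.153007e-05
9.450000e-01,1.170826e-05
9.550000e-01,1.190439e-05
9.650000e-01,1.382812e-05
9.750000e-01,1.404376e-05
9.850000e-01,3.553263e-06
9.950000e-01,1.081461e-05
1.005000e+00,3.659016e-06
1.015000e+00,1.117692e-05
1.025000e+00,7.578668e-06
1.035000e+00,5.740886e-06
1.045000e+00,1.939720e-06
1.055000e+00,3.946859e-06
1.065000e+00,1.999127e-06
1.075000e+00,2.020877e-06
1.095000e+00,4.190507e-06
1.105000e+00,6.354817e-06
1.115000e+00,4.296616e-06
1.125000e+00,2.166772e-06
1.135000e+00,2.210880e-06
1.145000e+00,4.477901e-06
1.155000e+00,2.258182e-06
1.165000e+00,2.275743e-06
1.175000e+00,4.638994e-06
1.185000e+00,7.073385e-06
1.205000e+00,2.413394e-06
1.215000e+00,2.426299e-06
1.255000e+00,5.108844e-06
1.285000e+00,2.657681e-06
1.295000e+00,2.684487e-06
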