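# element,S,Z,16,A,32.06
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,4.0598569522e+04,4.0541143225e+04,9.985854997780e-01,4.905512000399e-06,1.409594710042e-03
1.500000e-03,1.3700378681e+04,1.3683254635e+04,9.987500618702e-01,1.450838994673e-05,1.235429739807e-03
2.000000e-03,6.1441359546e+03,6.1355183602e+03,9.985973024918e-01,3.228868154722e-05,1.370408826697e-03
3.000000e-03,1.9164467544e+03,1.9118550820e+03,9.976034722952e-01,1.031195135784e-04,2.293408191264e-03
4.000000e-03,8.2000963387e+02,8.1689131633e+02,9.961953709002e-01,2.400797155960e-04,3.564549384161e-03
5.000000e-03,4.2002100691e+02,4.1765957224e+02,9.943733450730e-01,4.669285628038e-04,5.159726364218e-03
6.000000e-03,2.3582240894e+02,2.3394921268e+02,9.920472669630e-01,8.285019413493e-04,7.124231095665e-03
8.000000e-03,1.0013208907e+02,9.8854869687e+01,9.872153428681e-01,1.936643017704e-03,1.084801411424e-02
1.000000e-02,5.0243283549e+01,4.9271152447e+01,9.805796351583e-01,3.831143008082e-03,1.558922183362e-02
1.500000e-02,1.4510123668e+01,1.3902977693e+01,9.577977830830e-01,1.302749410283e-02,2.917472281415e-02
2.000000e-02,6.0413811776e+00,5.5929883614e+00,9.246714445970e-01,3.074330218836e-02,4.458525321467e-02
3.000000e-02,1.8393011897e+00,1.5322834081e+00,8.279984970214e-01,9.763106601321e-02,7.437043696536e-02
4.000000e-02,8.5608797962e-01,6.1187362432e-01,7.011435002164e-01,2.031753990718e-01,9.568110071177e-02
5.000000e-02,5.1340100560e-01,3.0406930550e-01,5.657356983203e-01,3.287046023637e-01,1.055596993160e-01
6.000000e-02,3.6309955297e-01,1.7563859906e-01,4.414355233969e-01,4.516185766799e-01,1.069458999232e-01
8.000000e-02,2.4069201596e-01,8.0816560573e-02,2.601124041035e-01,6.459158112873e-01,9.397178460924e-02
1.000000e-01,1.9278284503e-01,5.0610863489e-02,1.565161101939e-01,7.681822775124e-01,7.530161229371e-02
1.500000e-01,1.4801302003e-01,3.2254490976e-02,5.437571599799e-02,9.007501207923e-01,4.487416320974e-02
2.000000e-01,1.2899705787e-01,2.9507508226e-02,2.385088125027e-02,9.470423141148e-01,2.910680463489e-02
3.000000e-01,1.0859191633e-01,2.9306202234e-02,6.092365253245e-03,9.782235306622e-01,1.568410408455e-02
4.000000e-01,9.6278330526e-02,2.9585125351e-02,1.205917351739e-03,9.885505194356e-01,1.024356321271e-02
5.000000e-01,8.7794225838e-02,2.9667167706e-02,0.000000000000e+00,9.898949731778e-01,1.010502682216e-02
6.000000e-01,8.0987225508e-02,2.9546234176e-02,0.000000000000e+00,9.926820657003e-01,7.317934299706e-03
8.000000e-01,7.1063606316e-02,2.8857806911e-02,0.000000000000e+00,9.936961271510e-01,6.303872849011e-03
1.000000e+00,6.3972359039e-02,2.7932666368e-02,0.000000000000e+00,9.922591789284e-01,7.740821071639e-03
1.250000e+00,5.7220109203e-02,2.6704540850e-02,0.000000000000e+00,9.917571334175e-01,8.242866582491e-03
1.500000e+00,5.2371811831e-02,2.5508922783e-02,0.000000000000e+00,9.846164815909e-01,1.538351840910e-02
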