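# element,Mg,Z,12,A,24.305
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,1.6237755389e+04,1.6205712616e+04,9.980266264378e-01,1.213383920104e-05,1.961239723041e-03
1.500000e-03,5.4792906436e+03,5.4696756270e+03,9.982451031148e-01,3.588860762439e-05,1.719008277624e-03
2.000000e-03,2.4574627331e+03,2.4525816586e+03,9.980134648197e-01,7.986442038633e-05,1.906670759937e-03
3.000000e-03,7.6687622151e+02,7.6423599579e+02,9.965556907048e-01,2.549420639602e-04,3.189367231193e-03
4.000000e-03,3.2836075565e+02,3.2654091329e+02,9.944532313943e-01,5.931333343131e-04,4.953635271394e-03
5.000000e-03,1.6835241026e+02,1.6695424121e+02,9.916839471111e-01,1.152474355886e-03,7.163578533030e-03
6.000000e-03,9.4644995833e+01,9.3518998381e+01,9.880795607157e-01,2.042255627066e-03,9.878183657261e-03
8.000000e-03,4.0310890737e+01,3.9517478082e+01,9.802456288091e-01,4.759152405155e-03,1.499521878577e-02
1.000000e-02,2.0320255758e+01,1.9697531698e+01,9.691786744455e-01,9.371440751560e-03,2.144988480293e-02
1.500000e-02,5.9359516365e+00,5.5185256782e+00,9.288094604994e-01,3.150437014111e-02,3.968616935947e-02
2.000000e-02,2.5378540288e+00,2.2108406999e+00,8.685356213738e-01,7.240178428937e-02,5.906259433686e-02
3.000000e-02,8.5013907108e-01,6.0561085199e-01,7.014923200886e-01,2.089681331691e-01,8.953954674229e-02
4.000000e-02,4.5144142545e-01,2.4529242649e-01,5.178606909163e-01,3.811687325311e-01,1.009705765526e-01
5.000000e-02,3.0976339558e-01,1.2612743632e-01,3.636746871054e-01,5.389662363529e-01,9.735907654167e-02
6.000000e-02,2.4579345700e-01,7.7145111276e-02,2.520644655734e-01,6.600188667650e-01,8.791666766159e-02
8.000000e-02,1.9046003632e-01,4.2084462738e-02,1.263765170866e-01,8.075378613616e-01,6.608562155182e-02
1.000000e-01,1.6613858670e-01,3.1770659300e-02,6.953256408554e-02,8.818430833987e-01,4.862435251575e-02
1.500000e-01,1.3865066737e-01,2.7005224746e-02,2.205536129852e-02,9.512867345826e-01,2.665790411887e-02
2.000000e-01,1.2411095697e-01,2.7310791032e-02,9.368366880580e-03,9.737965255944e-01,1.683510752499e-02
3.000000e-01,1.0628672407e-01,2.8586324494e-02,2.334501161470e-03,9.887482707744e-01,8.917228064152e-03
4.000000e-01,9.4749991506e-02,2.9197090715e-02,4.571041333948e-04,9.937505817464e-01,5.792314120197e-03
5.000000e-01,8.6471075198e-02,2.9349806520e-02,0.000000000000e+00,9.942906818066e-01,5.709318193363e-03
6.000000e-01,7.9864359096e-02,2.9230166663e-02,0.000000000000e+00,9.958704407751e-01,4.129559224939e-03
8.000000e-01,7.0109518494e-02,2.8549103772e-02,0.000000000000e+00,9.964442650031e-01,3.555734996890e-03
1.000000e+00,6.3073690135e-02,2.7633859816e-02,0.000000000000e+00,9.956309920245e-01,4.369007975484e-03
1.250000e+00,5.6403860683e-02,2.6418872032e-02,0.000000000000e+00,9.953466062268e-01,4.653393773163e-03
1.500000e+00,5.1462863415e-02,2.5236043955e-02,0.000000000000e+00,9.912881375401e-01,8.711862459852e-03
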