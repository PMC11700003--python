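# element,C,Z,6,A,12.011
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,1.8554384233e+03,1.8471841378e+03,9.955510924896e-01,1.074395416541e-04,4.341467968755e-03
1.500000e-03,6.2603412740e+02,6.2345326961e+02,9.958765217919e-01,3.178113484462e-04,3.805666859660e-03
2.000000e-03,2.8093751609e+02,2.7955451756e+02,9.950744595264e-01,7.068333123721e-04,4.218707161244e-03
3.000000e-03,8.7926640371e+01,8.7111308596e+01,9.907140964310e-01,2.249742189503e-03,7.036161379546e-03
4.000000e-03,3.7828595988e+01,3.7221620759e+01,9.839145059371e-01,5.209185448638e-03,1.087630861427e-02
5.000000e-03,1.9531177350e+01,1.9031696783e+01,9.743302234897e-01,1.005098554023e-02,1.561879097006e-02
6.000000e-03,1.1091420371e+01,1.0661608813e+01,9.610464590581e-01,1.763222239567e-02,2.132131854625e-02
8.000000e-03,4.8510131063e+00,4.5069472228e+00,9.284677804281e-01,4.001345220205e-02,3.151876736989e-02
1.000000e-02,2.5477102754e+00,2.2484015151e+00,8.810995045844e-01,7.562614407676e-02,4.327435133884e-02
1.500000e-02,8.6583109800e-01,6.2225034623e-01,7.126470105331e-01,2.185316966881e-01,6.882129277884e-02
2.000000e-02,4.6732684482e-01,2.5020459299e-01,5.210539139096e-01,3.978154462991e-01,8.113063979126e-02
3.000000e-02,2.6368538922e-01,7.4039795056e-02,2.453153001393e-01,6.816641207460e-01,7.302057911465e-02
4.000000e-02,2.1066294070e-01,3.6674802734e-02,1.188180639535e-01,8.264507860111e-01,5.473115003543e-02
5.000000e-02,1.8848777051e-01,2.5573596960e-02,6.334908238617e-02,8.961793677403e-01,4.047154987356e-02
6.000000e-02,1.7611857606e-01,2.1881345364e-02,3.698126174930e-02,9.319829455572e-01,3.103579269349e-02
8.000000e-02,1.6129703113e-01,2.0724678397e-02,1.548485957868e-02,9.647767861527e-01,1.973835426867e-02
1.000000e-01,1.5146425918e-01,2.1643524684e-02,7.834947099206e-03,9.786741614038e-01,1.349089149703e-02
1.500000e-01,1.3469375740e-01,2.4537794521e-02,2.289943869676e-03,9.907689774198e-01,6.941078710511e-03
2.000000e-01,1.2292691224e-01,2.6571883746e-02,9.417197092389e-04,9.947589034035e-01,4.299376887287e-03
3.000000e-01,1.0659286861e-01,2.8696302416e-02,2.275559897901e-04,9.975233520289e-01,2.249091981317e-03
4.000000e-01,9.5410121502e-02,2.9501416152e-02,4.380277640948e-05,9.985011961690e-01,1.455001054550e-03
5.000000e-01,8.7115149238e-02,2.9695572703e-02,0.000000000000e+00,9.985665323595e-01,1.433467640500e-03
6.000000e-01,8.0554963042e-02,2.9574523385e-02,0.000000000000e+00,9.989644027737e-01,1.035597226294e-03
8.000000e-01,7.0746298646e-02,2.8885436982e-02,0.000000000000e+00,9.991086893023e-01,8.913106977031e-04
1.000000e+00,6.3607640997e-02,2.7959410658e-02,0.000000000000e+00,9.989041571967e-01,1.095842803332e-03
1.250000e+00,5.6869175976e-02,2.6730109264e-02,0.000000000000e+00,9.988325771982e-01,1.167422801788e-03
1.500000e+00,5.1728926199e-02,2.5533346446e-02,0.000000000000e+00,9.978077101896e-01,2.192289810438e-03
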