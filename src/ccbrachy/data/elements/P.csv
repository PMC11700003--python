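# element,P,Z,15,A,30.974
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,3.2151807609e+04,3.2102807401e+04,9.984759617270e-01,6.010729446356e-06,1.518027543587e-03
1.500000e-03,1.0849815357e+04,1.0835187577e+04,9.986517427199e-01,1.777734677413e-05,1.330479933335e-03
2.000000e-03,4.8658290792e+03,4.8584562175e+03,9.984846141281e-01,3.956323353439e-05,1.475822638379e-03
3.000000e-03,1.5178561051e+03,1.5139169434e+03,9.974040535290e-01,1.263410587184e-04,2.469605412325e-03
4.000000e-03,6.4954422352e+02,6.4686176602e+02,9.958679832917e-01,2.941055351805e-04,3.837911173119e-03
5.000000e-03,3.3276399822e+02,3.3072718988e+02,9.938736423322e-01,5.719033225040e-04,5.554454345250e-03
6.000000e-03,1.8687511025e+02,1.8525483219e+02,9.913180080790e-01,1.014529407830e-03,7.667462513190e-03
8.000000e-03,7.9391228464e+01,7.8279491502e+01,9.859608541156e-01,2.370215477544e-03,1.166893040683e-02
1.000000e-02,3.9867665471e+01,3.9016375148e+01,9.785591884474e-01,4.685145390896e-03,1.675566616167e-02
1.500000e-02,1.1530775994e+01,1.0991363150e+01,9.527809938026e-01,1.590783084452e-02,3.131117535289e-02
2.000000e-02,4.8206286855e+00,4.4171725560e+00,9.149585115595e-01,3.738699602202e-02,4.765449241850e-02
3.000000e-02,1.4913082777e+00,1.2094609101e+00,8.049261334971e-01,1.168452211781e-01,7.822864532484e-02
4.000000e-02,7.1118443941e-01,4.8383114726e-01,6.644446988362e-01,2.373257025709e-01,9.822959859293e-02
5.000000e-02,4.3842098694e-01,2.4165988189e-01,5.210594767273e-01,3.735155311393e-01,1.054249921334e-01
6.000000e-02,3.1821257152e-01,1.4086901289e-01,3.958686345698e-01,5.000548906669e-01,1.040764747633e-01
8.000000e-02,2.1929492791e-01,6.6814308685e-02,2.241012674120e-01,6.879335871097e-01,8.796514547834e-02
1.000000e-01,1.7974836690e-01,4.3494711854e-02,1.316452490604e-01,7.994756039471e-01,6.887914699249e-02
1.500000e-01,1.4133809465e-01,2.9789923602e-02,4.458081941498e-02,9.153401596441e-01,4.007902094093e-02
2.000000e-01,1.2415399504e-01,2.8053487881e-02,1.937762851766e-02,9.548298565664e-01,2.579251491597e-02
3.000000e-01,1.0504870082e-01,2.8312329767e-02,4.916199424527e-03,9.812562078171e-01,1.382759275842e-02
4.000000e-01,9.3287604519e-02,2.8686386396e-02,9.703616415497e-04,9.900131855334e-01,9.016452825096e-03
5.000000e-01,8.5088663413e-02,2.8788138741e-02,0.000000000000e+00,9.911077477154e-01,8.892252284646e-03
6.000000e-01,7.8517958289e-02,2.8670788434e-02,0.000000000000e+00,9.935625171922e-01,6.437482807802e-03
8.000000e-01,6.8905373970e-02,2.8002759055e-02,0.000000000000e+00,9.944552541188e-01,5.544745881214e-03
1.000000e+00,6.2018689214e-02,2.7105030139e-02,0.000000000000e+00,9.931901606746e-01,6.809839325386e-03
1.250000e+00,5.5469272630e-02,2.5913293599e-02,0.000000000000e+00,9.927480544435e-01,7.251945556526e-03
1.500000e+00,5.0725381285e-02,2.4753101324e-02,0.000000000000e+00,9.864540955632e-01,1.354590443682e-02
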