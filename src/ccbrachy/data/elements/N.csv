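# element,N,Z,7,A,14.007
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,3.0142925351e+03,3.0031247328e+03,9.962949213276e-01,6.616161881232e-05,3.638917053619e-03
1.500000e-03,1.0170434813e+03,1.0136008514e+03,9.966144903944e-01,1.957080623760e-04,3.189801543248e-03
2.000000e-03,4.5630690635e+02,4.5449516721e+02,9.960278707096e-01,4.353620139279e-04,3.536767276489e-03
3.000000e-03,1.4266274697e+02,1.4162357543e+02,9.927078471939e-01,1.387150165091e-03,5.905002641027e-03
4.000000e-03,6.1269282538e+01,6.0513418729e+01,9.876384896955e-01,3.217570523133e-03,9.143939781406e-03
5.000000e-03,3.1550171173e+01,3.0940278554e+01,9.806094936793e-01,6.224667815429e-03,1.316583850528e-02
6.000000e-03,1.7847510896e+01,1.7332087882e+01,9.709952558741e-01,1.096219170695e-02,1.804255241892e-02
8.000000e-03,7.7249370039e+00,7.3254916873e+00,9.479109808933e-01,2.513763127808e-02,2.695138782860e-02
1.000000e-02,3.9924201311e+00,3.6531574567e+00,9.141173969015e-01,4.827992509082e-02,3.760267800773e-02
1.500000e-02,1.2776838841e+00,1.0124749798e+00,7.883439843504e-01,1.481511506733e-01,6.350486497636e-02
2.000000e-02,6.3626260404e-01,4.0535287135e-01,6.265462817566e-01,2.923121049081e-01,8.114161333526e-02
3.000000e-02,3.1237039139e-01,1.1568992270e-01,3.404045182560e-01,5.756618752088e-01,8.393360653527e-02
4.000000e-02,2.3113976629e-01,5.2913887627e-02,1.785274726802e-01,7.535486524021e-01,6.792387491769e-02
5.000000e-02,1.9910564483e-01,3.3367779888e-02,9.908826362710e-02,8.487413746321e-01,5.217036174075e-02
6.000000e-02,1.8243190131e-01,2.6155789232e-02,5.909674081218e-02,9.001050001949e-01,4.079825899288e-02
8.000000e-02,1.6416201212e-01,2.2380954907e-02,2.525765577446e-02,9.483341288129e-01,2.640821541268e-02
1.000000e-01,1.5305280066e-01,2.2439803855e-02,1.290060821868e-02,9.689198078014e-01,1.817958397987e-02
1.500000e-01,1.3529431579e-01,2.4754726938e-02,3.808608216778e-03,9.867818322595e-01,9.409559523738e-03
2.000000e-01,1.2324717842e-01,2.6661092065e-02,1.573692335869e-03,9.925871538970e-01,5.839153767159e-03
3.000000e-01,1.0674040692e-01,2.8724792243e-02,3.822821868040e-04,9.965594119291e-01,3.058305884049e-03
4.000000e-01,9.5502876808e-02,2.9516572240e-02,7.382964243631e-05,9.979468517372e-01,1.979318620372e-03
5.000000e-01,8.7196542238e-02,2.9707939675e-02,0.000000000000e+00,9.980499007186e-01,1.950099281381e-03
6.000000e-01,8.0618648172e-02,2.9586839945e-02,0.000000000000e+00,9.985909640397e-01,1.409035960275e-03
8.000000e-01,7.0798541581e-02,2.8897466566e-02,0.000000000000e+00,9.987872174548e-01,1.212782545242e-03
1.000000e+00,6.3659312298e-02,2.7971054590e-02,0.000000000000e+00,9.985090261940e-01,1.490973805982e-03
1.250000e+00,5.6916843910e-02,2.6741241244e-02,0.000000000000e+00,9.984116774412e-01,1.588322558777e-03
1.500000e+00,5.1791437934e-02,2.5543980023e-02,0.000000000000e+00,9.970184103861e-01,2.981589613906e-03
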