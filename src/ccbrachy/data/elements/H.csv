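# element,H,Z,1,A,1.008
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,1.3821054244e+01,1.2981559060e+01,9.392038701928e-01,2.864421374950e-02,3.215191605773e-02
1.500000e-03,4.9077688182e+00,4.3823662364e+00,8.927099007957e-01,8.051016140726e-02,2.677993779709e-02
2.000000e-03,2.4242616602e+00,1.9660494558e+00,8.103577133421e-01,1.626726864255e-01,2.696960023239e-02
3.000000e-03,1.0391259532e+00,6.1442964152e-01,5.891034628535e-01,3.780527701172e-01,3.284376702931e-02
4.000000e-03,6.7559809024e-01,2.6456985768e-01,3.871507622631e-01,5.792539615850e-01,3.359527615186e-02
5.000000e-03,5.4041351179e-01,1.3746333887e-01,2.474567728056e-01,7.214035202613e-01,3.113970693314e-02
6.000000e-03,4.7633692287e-01,7.9352634736e-02,1.572563703577e-01,8.153561630258e-01,2.738746661653e-02
8.000000e-03,4.2556939811e-01,3.7485616718e-02,7.437377749213e-02,9.058065640872e-01,1.981965842069e-02
1.000000e-02,4.0449599298e-01,2.2954573112e-02,3.899884254785e-02,9.459651938632e-01,1.503596358893e-02
1.500000e-02,3.8318667437e-01,1.4499123829e-02,1.079280550963e-02,9.806287115356e-01,8.578482954739e-03
2.000000e-02,3.7287659825e-01,1.4888212610e-02,4.232453342916e-03,9.901582890483e-01,5.609257608748e-03
3.000000e-02,3.5842559971e-01,1.8975872336e-02,1.115608339281e-03,9.959209444023e-01,2.963447258432e-03
4.000000e-02,3.4654389194e-01,2.3274448346e-02,4.317469228201e-04,9.977328588925e-01,1.835394184641e-03
5.000000e-02,3.3595403769e-01,2.7144076035e-02,2.069897925517e-04,9.985403939837e-01,1.252616223772e-03
6.000000e-02,3.2631082746e-01,3.0557659464e-02,1.137937595563e-04,9.989621436112e-01,9.240626292082e-04
8.000000e-02,3.0923360507e-01,3.6211635657e-02,4.452734668795e-05,9.993875155789e-01,5.679570744385e-04
1.000000e-01,2.9450409418e-01,4.0632489715e-02,2.164328384137e-05,9.995955986414e-01,3.827580747621e-04
1.500000e-01,2.6507840475e-01,4.8119761888e-02,5.960907329439e-06,9.997994739787e-01,1.945651139495e-04
2.000000e-01,2.4287642088e-01,5.2540995072e-02,2.361100680947e-06,9.998775972318e-01,1.200416675210e-04
3.000000e-01,2.1117672016e-01,5.6941244126e-02,5.426849331993e-07,9.999368313819e-01,6.262593320386e-05
4.000000e-01,1.8920301183e-01,5.8579931906e-02,1.009165140411e-07,9.999594233623e-01,4.047572115202e-05
5.000000e-01,1.7276485229e-01,5.8973796915e-02,0.000000000000e+00,9.999601258839e-01,3.987411609526e-05
6.000000e-01,1.5981671734e-01,5.8733399533e-02,0.000000000000e+00,9.999712044181e-01,2.879558189333e-05
8.000000e-01,1.4037656324e-01,5.7364911308e-02,0.000000000000e+00,9.999752198963e-01,2.478010374188e-05
1.000000e+00,1.2618674231e-01,5.5525873249e-02,0.000000000000e+00,9.999695274566e-01,3.047254340111e-05
1.250000e+00,1.1281091407e-01,5.3084547349e-02,0.000000000000e+00,9.999675347410e-01,3.246525904769e-05
1.500000e+00,1.0251188224e-01,5.0707841296e-02,0.000000000000e+00,9.999389729883e-01,6.102701171657e-05
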