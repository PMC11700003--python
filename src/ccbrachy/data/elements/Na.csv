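# element,Na,Z,11,A,22.99
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,1.1966066515e+04,1.1939943254e+04,9.978168571400e-01,1.595662029856e-05,2.167186239700e-03
1.500000e-03,4.0377733657e+03,4.0299133907e+03,9.980532511302e-01,4.719620744181e-05,1.899552662327e-03
2.000000e-03,1.8110028685e+03,1.8069978885e+03,9.977881216442e-01,1.050241655845e-04,2.106854190203e-03
3.000000e-03,5.6524931558e+02,5.6306926064e+02,9.961412547638e-01,3.351929049907e-04,3.523552331161e-03
4.000000e-03,2.4209894599e+02,2.4058711153e+02,9.937493039973e-01,7.796124630457e-04,5.471083539611e-03
5.000000e-03,1.2417621961e+02,1.2300792910e+02,9.905771686355e-01,1.514189631805e-03,7.908641732692e-03
6.000000e-03,6.9849343976e+01,6.8902854317e+01,9.864188593366e-01,2.681720546678e-03,1.089942011673e-02
8.000000e-03,2.9791445259e+01,2.9116113911e+01,9.772369127908e-01,6.240631346388e-03,1.652245586284e-02
1.000000e-02,1.5049468619e+01,1.4513453834e+01,9.641530513047e-01,1.226259715256e-02,2.358435154276e-02
1.500000e-02,4.4258409032e+00,4.0577777609e+00,9.157083558293e-01,4.094807124287e-02,4.334357292782e-02
2.000000e-02,1.9177670627e+00,1.6240601255e+00,8.435022032621e-01,9.285133363457e-02,6.364646310329e-02
3.000000e-02,6.7080779762e-01,4.4561829675e-01,6.509452499008e-01,2.566492680550e-01,9.240548204415e-02
4.000000e-02,3.7477381080e-01,1.8205057669e-01,4.560018447181e-01,4.449564791765e-01,9.904167610542e-02
5.000000e-02,2.6859736773e-01,9.5304062783e-02,3.062059206852e-01,6.023625968436e-01,9.143148247125e-02
6.000000e-02,2.1999817916e-01,5.9906092715e-02,2.053932663438e-01,7.146208363066e-01,7.998589734960e-02
8.000000e-02,1.7682656887e-01,3.4984214338e-02,9.911465663010e-02,8.429218845063e-01,5.796345886358e-02
1.000000e-01,1.5696009905e-01,2.7994715995e-02,5.352236983929e-02,9.045668205503e-01,4.191080961038e-02
1.500000e-01,1.3304932615e-01,2.5425964807e-02,1.667597243342e-02,9.607022744685e-01,2.262175309806e-02
2.000000e-01,1.1966782311e-01,2.6182304854e-02,7.038111492431e-03,9.787438528360e-01,1.421803567154e-02
3.000000e-01,1.0279450479e-01,2.7641838440e-02,1.744474400491e-03,9.907474269790e-01,7.508098620465e-03
4.000000e-01,9.1726438279e-02,2.8284145569e-02,3.406849848223e-04,9.947870856298e-01,4.872229385400e-03
5.000000e-01,8.3722605689e-02,2.8442864732e-02,0.000000000000e+00,9.951982080178e-01,4.801791982211e-03
6.000000e-01,7.7345411895e-02,2.8326921880e-02,0.000000000000e+00,9.965277329051e-01,3.472267094914e-03
8.000000e-01,6.7904469207e-02,2.7666904592e-02,0.000000000000e+00,9.970104970704e-01,2.989502929639e-03
1.000000e+00,6.1081988226e-02,2.6779942696e-02,0.000000000000e+00,9.963262560471e-01,3.673743952889e-03
1.250000e+00,5.4620291668e-02,2.5602499392e-02,0.000000000000e+00,9.960869482439e-01,3.913051756099e-03
1.500000e+00,4.9803206849e-02,2.4456222022e-02,0.000000000000e+00,9.926694152243e-01,7.330584775745e-03
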