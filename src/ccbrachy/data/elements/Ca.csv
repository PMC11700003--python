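# element,Ca,Z,20,A,40.078
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,8.1960595970e+04,8.1870985895e+04,9.989066640950e-01,2.429726869938e-06,1.090906178101e-03
1.500000e-03,2.7659349759e+04,2.7632706914e+04,9.990367298939e-01,7.185836228485e-06,9.560842698871e-04
2.000000e-03,1.2403751025e+04,1.2390398193e+04,9.989234222593e-01,1.599283949055e-05,1.060584901174e-03
3.000000e-03,3.8679662523e+03,3.8609028118e+03,9.981735657866e-01,5.108841477284e-05,1.775345798604e-03
4.000000e-03,1.6544352712e+03,1.6496731425e+03,9.971206829827e-01,1.189849773941e-04,2.760332039880e-03
5.000000e-03,8.4702271967e+02,8.4344250668e+02,9.957709618011e-01,2.315228626028e-04,3.997515336305e-03
6.000000e-03,4.7526548037e+02,4.7244746506e+02,9.940659449107e-01,4.110643561565e-04,5.522990733129e-03
8.000000e-03,2.0151798483e+02,1.9962989999e+02,9.906161245621e-01,9.622247642575e-04,8.421650673610e-03
1.000000e-02,1.0090976424e+02,9.9497158684e+01,9.859655099505e-01,1.907395159705e-03,1.212709488978e-02
1.500000e-02,2.9082228248e+01,2.8237023074e+01,9.707581486694e-01,6.499378218403e-03,2.274247311224e-02
2.000000e-02,1.2002062785e+01,1.1402201837e+01,9.494623417924e-01,1.547384876394e-02,3.506380944370e-02
3.000000e-02,3.5182922903e+00,3.1343590811e+00,8.882192652886e-01,5.103597975920e-02,6.074475495224e-02
4.000000e-02,1.5387333971e+00,1.2484655860e+00,8.037996428401e-01,1.130299747953e-01,8.317038236456e-02
5.000000e-02,8.5385063144e-01,6.1405250117e-01,7.032067079344e-01,1.976278227379e-01,9.916546932772e-02
6.000000e-02,5.5687052805e-01,3.4758223664e-01,5.966015641417e-01,2.944494640896e-01,1.089489717686e-01
8.000000e-02,3.2110556590e-01,1.4852025990e-01,4.058230536908e-01,4.841247177019e-01,1.100522286073e-01
1.000000e-01,2.3377050335e-01,8.3444041971e-02,2.695307081375e-01,6.334472379132e-01,9.702205394925e-02
1.500000e-01,1.6059583143e-01,4.1110144306e-02,1.052691034966e-01,8.301134888148e-01,6.461740768856e-02
2.000000e-01,1.3451258567e-01,3.2918626974e-02,4.824671741644e-02,9.081419927774e-01,4.361128980615e-02
3.000000e-01,1.1028396494e-01,3.0046226023e-02,1.272850112564e-02,9.631428858883e-01,2.412861298611e-02
4.000000e-01,9.6957125531e-02,2.9714197982e-02,2.551459874804e-03,9.815562169748e-01,1.589232315036e-02
5.000000e-01,8.8286645923e-02,2.9664946998e-02,0.000000000000e+00,9.843001348420e-01,1.569986515795e-02
6.000000e-01,8.1314509131e-02,2.9544022521e-02,0.000000000000e+00,9.886126020362e-01,1.138739796383e-02
8.000000e-01,7.1310254522e-02,2.8855646788e-02,0.000000000000e+00,9.901850019545e-01,9.814998045502e-03
1.000000e+00,6.4246098804e-02,2.7930575495e-02,0.000000000000e+00,9.879574030938e-01,1.204259690625e-02
1.250000e+00,5.7481113658e-02,2.6702541907e-02,0.000000000000e+00,9.871799625103e-01,1.282003748967e-02
1.500000e+00,5.2821042953e-02,2.5507013337e-02,0.000000000000e+00,9.761694635771e-01,2.383053642286e-02
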