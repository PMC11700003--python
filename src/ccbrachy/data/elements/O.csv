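# element,O,Z,8,A,15.999
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,4.5905991463e+03,4.5760653889e+03,9.968339326257e-01,4.346767251762e-05,3.122599701809e-03
1.500000e-03,1.5489305517e+03,1.5444923142e+03,9.971342689547e-01,1.285761830305e-04,2.737154862290e-03
2.000000e-03,6.9485189493e+02,6.9254482259e+02,9.966786538526e-01,2.860616020003e-04,3.035284545353e-03
3.000000e-03,2.1709866880e+02,2.1580088275e+02,9.940168509115e-01,9.120552272818e-04,5.071093861259e-03
4.000000e-03,9.3135510151e+01,9.2207621820e+01,9.900209249770e-01,2.117872488562e-03,7.861202534430e-03
5.000000e-03,4.7882290188e+01,4.7144824444e+01,9.845590515042e-01,4.103809784544e-03,1.133713871127e-02
6.000000e-03,2.7023254803e+01,2.6408910479e+01,9.771831683254e-01,7.244053173913e-03,1.557277850073e-02
8.000000e-03,1.1624252508e+01,1.1160812625e+01,9.598786579148e-01,1.671469668365e-02,2.340664540159e-02
1.000000e-02,5.9501086135e+00,5.5646723962e+00,9.346137967665e-01,3.241321934528e-02,3.297298388819e-02
1.500000e-02,1.8356791582e+00,1.5454685790e+00,8.390600609531e-01,1.031753393601e-01,5.776459968677e-02
2.000000e-02,8.6468223085e-01,6.1782941463e-01,7.067576023963e-01,2.152141894376e-01,7.802820816609e-02
3.000000e-02,3.7776614058e-01,1.7294448457e-01,4.330234314444e-01,4.762758247953e-01,9.070074376036e-02
4.000000e-02,2.5843140102e-01,7.5296465974e-02,2.462580916497e-01,6.743493178905e-01,7.939259045973e-02
5.000000e-02,2.1314543669e-01,4.4132729149e-02,1.430305526774e-01,7.932811683891e-01,6.368827893346e-02
6.000000e-02,1.9071304879e-01,3.2069304212e-02,8.749268645995e-02,8.615049694160e-01,5.100234412402e-02
8.000000e-02,1.6786693269e-01,2.4678262169e-02,3.832438673009e-02,9.279255418114e-01,3.375007145851e-02
1.000000e-01,1.5508506920e-01,2.3546352649e-02,1.979243108013e-02,9.567607804885e-01,2.344678843135e-02
1.500000e-01,1.3604866967e-01,2.5056966969e-02,5.908823189738e-03,9.818624096409e-01,1.222876716935e-02
2.000000e-01,1.2364621719e-01,2.6785369991e-02,2.453308935438e-03,9.899403780324e-01,7.606313032197e-03
3.000000e-01,1.0692365692e-01,2.8764167408e-02,5.989728715019e-04,9.954111079193e-01,3.989919209199e-03
4.000000e-01,9.5618539049e-02,2.9537215796e-02,1.160272428081e-04,9.973004149012e-01,2.583557855985e-03
5.000000e-01,8.7297676288e-02,2.9724651436e-02,0.000000000000e+00,9.974544511650e-01,2.545548834981e-03
6.000000e-01,8.0698792407e-02,2.9603483582e-02,0.000000000000e+00,9.981604199808e-01,1.839580019216e-03
8.000000e-01,7.0864667700e-02,2.8913722407e-02,0.000000000000e+00,9.984165453652e-01,1.583454634762e-03
1.000000e+00,6.3724194663e-02,2.7986789292e-02,0.000000000000e+00,9.980534940665e-01,1.946505933519e-03
1.250000e+00,5.6976551379e-02,2.6756284132e-02,0.000000000000e+00,9.979264644467e-01,2.073535553313e-03
1.500000e+00,5.1867870708e-02,2.5558349410e-02,0.000000000000e+00,9.961092300999e-01,3.890769900063e-03
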