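energy_MeV,weight
# Bare-point Ir-192 emission spectrum: gamma lines plus Pt/Os K x-rays,
# photons per 100 decays (relative weights; normalized on load).
6.1490e-02,1.19
6.3000e-02,2.05
6.5120e-02,2.62
6.6830e-02,4.46
7.1080e-02,0.24
7.1410e-02,0.46
7.3360e-02,1.60
7.5740e-02,0.53
7.7830e-02,0.36
1.3634e-01,0.199
2.0131e-01,0.471
2.0579e-01,3.34
2.8327e-01,0.266
2.9596e-01,28.71
3.0846e-01,29.70
3.1651e-01,82.86
3.7449e-01,0.727
4.1647e-01,0.670
4.6807e-01,47.84
4.8458e-01,3.189
4.8906e-01,0.438
5.8858e-01,4.522
6.0441e-01,8.216
6.1246e-01,5.34
7.6580e-01,0.013
8.8454e-01,0.291
1.0615e+00,0.053
1.0899e+00,0.011
1.3782e+00,0.0071
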