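"""Physical constants (CODATA-2018 rounded) used across the package."""

#: classical electron radius [cm]
R_E = 2.8179403262e-13

#: Thomson cross section [cm^2]
SIGMA_T = 6.6524587321e-25

#: Avogadro constant [1/mol]
N_A = 6.02214076e23

#: electron rest energy [MeV]
MEC2 = 0.51099895

#: photon transport cutoff [MeV] (photons below this deposit locally)
E_CUTOFF = 1.0e-3

#: upper edge of the tabulated energy range [MeV]
E_MAX = 1.5
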