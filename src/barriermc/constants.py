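"""Physical constants used throughout the package (CODATA 2018)."""

R0_CM = 2.8179403262e-13  #: classical electron radius, cm
MEC2_MEV = 0.51099895  #: electron rest energy, MeV
AVOGADRO = 6.02214076e23  #: 1/mol
MEV_TO_J = 1.602176634e-13  #: J per MeV
PAIR_THRESHOLD_MEV = 2 * MEC2_MEV  #: photon pair-production threshold

#: validity range of the embedded interaction tables, MeV
E_MIN_MEV = 0.01
E_MAX_MEV = 25.0
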