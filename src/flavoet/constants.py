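"""Physical constants in the package's working units (eV, nm, ps, K)."""

#: Coulomb constant e^2 / (4 pi eps0), in eV nm.
COULOMB_EV_NM = 1.439964

#: Boltzmann constant, eV / K.
BOLTZMANN_EV_PER_K = 8.617333e-5

#: Default absolute temperature, K.
DEFAULT_TEMPERATURE_K = 298.0
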