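"""Physical constants and unit helpers (SI internally)."""

#: Boltzmann constant, J/K (2019 SI exact value)
K_B = 1.380649e-23

#: Default absolute temperature, K (25 degC); experiments span 18-30 degC
DEFAULT_T = 298.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


# display-unit scale factors (SI value * factor = display value)
UM_PER_M = 1e6
NM_PER_M = 1e9
FN_PER_N = 1e15
PN_PER_N = 1e12
UN_PER_M_PER_N_PER_M = 1e6  # N/m -> uN/m
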