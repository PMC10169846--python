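"""Physical constants and electrolyte defaults used across the transport models.

All pore dimensions are nanometres, concentrations mol L^-1, mobilities
m^2 V^-1 s^-1, currents pA, potentials mV, conductances nS unless a name
says otherwise.
"""

# elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19
# gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314462618
# Faraday constant, C mol^-1
FARADAY = 96485.33212

# Avogadro's number per cubic metre per (mol / L): converts c in mol L^-1
# to an ion number density in m^-3.
IONS_PER_M3_PER_MOLAR = 6.02e26

# Bulk ionic mobilities in water at 25 degC, m^2 V^-1 s^-1
# (literature infinite-dilution values for K+ and Cl-).
MU_K_BULK = 7.62e-8
MU_CL_BULK = 7.91e-8

DEFAULT_TEMPERATURE_K = 298.15

# Mean molal activity coefficients of aqueous KCl at 25 degC.
# Interpolated at intermediate concentrations; Davies equation used as a
# fallback outside the table range.
KCL_ACTIVITY_COEFFICIENTS = {
    0.001: 0.965,
    0.01: 0.901,
    0.1: 0.770,
    0.5: 0.649,
    1.0: 0.604,
    2.0: 0.573,
}
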