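"""Physical constants and unit conventions.

All internal energies are J mol⁻¹, volumes L, concentrations mol L⁻¹,
temperatures K.  Calorimeter-native calories are converted on I/O only.
"""

#: Gas constant, J mol⁻¹ K⁻¹.
GAS_CONSTANT = 8.314

#: Thermochemical calorie, J.
CAL_TO_J = 4.184

#: Default standard concentration c° for the Gibbs energy, mol L⁻¹.
STANDARD_CONCENTRATION = 1.0

#: Mole-fraction standard state expressed as a concentration (≈ molarity of
#: pure water); selectable alternative to the 1 M convention.
MOLE_FRACTION_STANDARD = 55.5

#: Offset between °C and K.
CELSIUS_OFFSET = 273.15
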