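"""Physical constants and thermal-voltage helpers.

All voltages in the package are millivolts, currents picoamps, conductances
nanosiemens, capacitances picofarads, times milliseconds (seconds where noted),
concentrations millimolar. This unit system makes the membrane equation
dV/dt = I/C come out directly in mV/ms.
"""

FARADAY = 96485.332  # C / mol
GAS_CONSTANT = 8.314462  # J / (mol K)
ZERO_CELSIUS = 273.15  # K

#: Default recording temperature (deg C); room-temperature patch clamp.
DEFAULT_TEMPERATURE_C = 19.0


def rt_over_f(temperature_c: float = DEFAULT_TEMPERATURE_C) -> float:
    """Thermal voltage RT/F in mV at the given temperature (deg C).

    At 19 deg C this is ~25.17 mV, the slope used in every Boltzmann and
    Nernst expression in the package.
    """
    t_kelvin = ZERO_CELSIUS + temperature_c
    return 1e3 * GAS_CONSTANT * t_kelvin / FARADAY
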